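"""Model/Results front-end over the haplotype-copying machinery.

``LiStephensModel`` holds a reference panel (and optionally a typed-marker
mask); ``fit()`` runs leave-one-haplotype-out EM and returns a
``LiStephensResults`` carrying the parameter estimates, their convergence
diagnostics, and imputation methods bound to those estimates::

    model = LiStephensModel(panel)
    res = model.fit()
    print(res.summary())
    dosages = res.impute(target_alleles, mask)
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import estimate as _est
from . import hmm as _hmm

__all__ = ["LiStephensModel", "LiStephensResults"]


class LiStephensModel:
    """Li-Stephens haplotype-copying model over a fixed reference panel."""

    def __init__(self, panel: _hmm.HaplotypePanel):
        self.panel = panel

    @classmethod
    def from_vcf(cls, path: str) -> "LiStephensModel":
        from .vcfio import read_panel

        return cls(read_panel(path))

    def fit(self, config: _est.EMConfig | None = None, **kwargs) -> "LiStephensResults":
        """Estimate theta/epsilon by leave-one-haplotype-out EM.

        Keyword arguments are forwarded into :class:`~imputeqc.estimate.EMConfig`
        when no explicit config is given.
        """
        cfg = config or _est.EMConfig(**kwargs)
        params = _est.estimate_params(self.panel, cfg)
        return LiStephensResults(model=self, params=params)

    def with_params(self, params: _hmm.HMMParams) -> "LiStephensResults":
        """Results object around externally supplied parameters (genetic
        map, manual, or deserialized)."""
        return LiStephensResults(model=self, params=params)


@dataclasses.dataclass
class LiStephensResults:
    """Fitted parameters plus imputation methods bound to them."""

    model: LiStephensModel
    params: _hmm.HMMParams

    @property
    def theta(self) -> np.ndarray:
        return self.params.theta

    @property
    def epsilon(self) -> np.ndarray:
        return self.params.epsilon

    @property
    def total_theta(self) -> float:
        return _est.total_theta(self.params)

    @property
    def converged(self) -> bool:
        return bool(self.params.diagnostics.get("converged", True))

    @property
    def loglik(self) -> float | None:
        trace = self.params.diagnostics.get("loglik") or []
        return trace[-1] if trace else None

    def scale(self, fold: float) -> "LiStephensResults":
        """New results with every interval theta multiplied by ``fold``."""
        return LiStephensResults(
            model=self.model, params=_hmm.scale_theta(self.params, fold)
        )

    def impute(self, target_alleles, mask) -> _hmm.DosageSet:
        return _hmm.impute(target_alleles, self.model.panel, self.params, mask)

    def loo_dosage(self, target_alleles, mask) -> np.ndarray:
        return _hmm.loo_dosage(target_alleles, self.model.panel, self.params, mask)

    def forward_backward(self, target_alleles, mask) -> np.ndarray:
        return _hmm.forward_backward(target_alleles, self.model.panel, self.params, mask)

    def summary(self) -> str:
        p = self.model.panel
        d = self.params.diagnostics
        th, ep = self.params.theta, self.params.epsilon
        lines = [
            "Li-Stephens haplotype-copying model",
            "=" * 46,
            f"{'Markers:':<28}{p.n_markers}",
            f"{'Panel haplotypes:':<28}{p.n_haplotypes}",
            f"{'Parameter provenance:':<28}{self.params.provenance}",
        ]
        if d.get("n_iter") is not None:
            lines.append(f"{'EM iterations:':<28}{d.get('n_iter')}")
            lines.append(f"{'Converged:':<28}{self.converged}")
        if self.loglik is not None:
            lines.append(f"{'Held-out log-likelihood:':<28}{self.loglik:.3f}")
        lines += [
            "-" * 46,
            f"{'Total theta:':<28}{self.total_theta:.4f}",
            f"{'Mean theta / interval:':<28}{th.mean():.6f}",
            f"{'Median theta / interval:':<28}{np.median(th):.6f}",
            f"{'Mean epsilon / marker:':<28}{ep.mean():.6f}",
        ]
        flags = d.get("flags") or []
        if flags:
            lines.append(f"{'Flags:':<28}{','.join(flags)}")
        lines.append("=" * 46)
        return "\n".join(lines)
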