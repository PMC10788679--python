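"""Minimal Li-Stephens haplotype-copying HMM for genotype imputation.

A target haplotype is modelled as an imperfect mosaic of the reference panel
haplotypes.  The hidden state at marker m is the panel haplotype being
copied.  Between adjacent markers the template is redrawn with probability
``theta`` (the template switching rate, modelling recombination and panel
relatedness); the redraw is uniform over all H templates, so the kernel is

    stay on h:            (1 - theta) + theta / H
    move to each h' != h: theta / H

At a typed (array-observed) marker the observed allele matches the copied
template with probability ``1 - epsilon`` and mismatches with probability
``epsilon`` (genotyping error, gene conversion, recurrent mutation).
Untyped markers emit nothing and are imputed from the posterior copying
probabilities: ``HDS(m) = sum_h P(h at m | data) * allele(m, h)``.

The recursions are rescaled per marker, so regions of 1e5 markers do not
underflow.  All public entry points accept one target haplotype or a batch
(markers x targets); internally everything is vectorised over targets in
memory-bounded chunks.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "THETA_FLOOR",
    "THETA_CEIL",
    "EPSILON_FLOOR",
    "EPSILON_CEIL",
    "MAX_MARKERS",
    "MAX_HAPLOTYPES",
    "HaplotypePanel",
    "HMMParams",
    "DosageSet",
    "make_mask",
    "forward_backward",
    "impute",
    "loo_dosage",
    "scale_theta",
]

THETA_FLOOR = 1e-10
THETA_CEIL = 1.0 - 1e-10
EPSILON_FLOOR = 1e-6
EPSILON_CEIL = 0.49

# single-region operation only; larger inputs must be windowed by the caller
MAX_MARKERS = 100_000
MAX_HAPLOTYPES = 1_000

#: cap on floats held in the stored forward pass (~160 MB)
_CHUNK_BUDGET = 20_000_000


@dataclasses.dataclass
class HaplotypePanel:
    """Phased reference haplotypes: a markers x haplotypes 0/1 matrix.

    ``markers`` carries variant metadata (chrom, pos, id, ref, alt) with
    1-based, strictly increasing positions; ``ancestry`` optionally labels
    each haplotype column.
    """

    alleles: np.ndarray
    markers: pd.DataFrame
    ancestry: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.int8))
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a markers x haplotypes matrix")
        if self.alleles.shape[1] < 1:
            raise ValueError("panel needs at least one haplotype")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0 (ref) or 1 (alt)")
        if len(self.markers) != self.alleles.shape[0]:
            raise ValueError("markers table does not match allele matrix")
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.markers.columns:
                raise ValueError(f"markers table lacks required column {col!r}")
        pos = np.asarray(self.markers["pos"], dtype=np.int64)
        chroms = np.asarray(self.markers["chrom"])
        for c in pd.unique(chroms):
            pc = pos[chroms == c]
            if not np.all(np.diff(pc) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.ancestry is not None:
            self.ancestry = np.asarray(self.ancestry)
            if self.ancestry.shape != (self.alleles.shape[1],):
                raise ValueError("ancestry labels do not match haplotype count")

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def variant_keys(self) -> list[str]:
        m = self.markers
        return [
            f"{c}:{p}:{r}:{a}"
            for c, p, r, a in zip(m["chrom"], m["pos"], m["ref"], m["alt"])
        ]

    def take_haplotypes(self, idx: Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            markers=self.markers.reset_index(drop=True),
            ancestry=None if self.ancestry is None else self.ancestry[idx],
        )

    @staticmethod
    def hstack(panels: Sequence["HaplotypePanel"]) -> "HaplotypePanel":
        """Concatenate haplotype blocks sharing an identical marker set."""
        first = panels[0]
        for p in panels[1:]:
            if not first.markers[["chrom", "pos", "ref", "alt"]].equals(
                p.markers[["chrom", "pos", "ref", "alt"]]
            ):
                raise ValueError("panels have different marker sets")
        anc = None
        if all(p.ancestry is not None for p in panels):
            anc = np.concatenate([p.ancestry for p in panels])
        return HaplotypePanel(
            alleles=np.hstack([p.alleles for p in panels]),
            markers=first.markers.reset_index(drop=True),
            ancestry=anc,
        )


@dataclasses.dataclass
class HMMParams:
    """Per-interval switching rates and per-marker error rates.

    ``theta`` has length ``n_markers - 1`` (interval between markers m and
    m+1), ``epsilon`` length ``n_markers``.  Values are clamped into open
    ranges on construction so the recursions never degenerate.
    """

    theta: np.ndarray
    epsilon: np.ndarray
    provenance: str = "manual"
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.clip(np.asarray(self.theta, dtype=float), THETA_FLOOR, THETA_CEIL)
        self.epsilon = np.clip(
            np.asarray(self.epsilon, dtype=float), EPSILON_FLOOR, EPSILON_CEIL
        )
        if self.theta.ndim != 1 or self.epsilon.ndim != 1:
            raise ValueError("theta and epsilon must be one-dimensional")
        if self.epsilon.size != self.theta.size + 1:
            raise ValueError(
                f"epsilon length {self.epsilon.size} must be theta length + 1 "
                f"({self.theta.size + 1})"
            )

    @property
    def n_markers(self) -> int:
        return self.epsilon.size

    @classmethod
    def constant(
        cls,
        n_markers: int,
        theta: float = 0.01,
        epsilon: float = 1e-3,
        provenance: str = "manual",
    ) -> "HMMParams":
        return cls(
            theta=np.full(max(n_markers - 1, 0), theta),
            epsilon=np.full(n_markers, epsilon),
            provenance=provenance,
        )


def scale_theta(params: HMMParams, fold: float) -> HMMParams:
    """Multiply every interval's theta by ``fold`` (clamped); epsilon kept."""
    if not fold > 0:
        raise ValueError(f"fold must be positive, got {fold}")
    return HMMParams(
        theta=np.clip(params.theta * fold, THETA_FLOOR, THETA_CEIL),
        epsilon=params.epsilon.copy(),
        provenance="manual",
        diagnostics=dict(params.diagnostics, scaled_fold=fold),
    )


@dataclasses.dataclass
class DosageSet:
    """Imputed haploid dosages (markers x target haplotypes) in [0, 1]."""

    hds: np.ndarray

    def __post_init__(self) -> None:
        self.hds = np.asarray(self.hds, dtype=float)
        if self.hds.ndim != 2:
            raise ValueError("hds must be markers x haplotypes")
        if self.hds.min() < -1e-9 or self.hds.max() > 1 + 1e-9:
            raise ValueError("hds entries must lie in [0, 1]")
        np.clip(self.hds, 0.0, 1.0, out=self.hds)

    @property
    def ds(self) -> np.ndarray:
        """Diploid dosages: consecutive haplotype columns summed pairwise."""
        if self.hds.shape[1] % 2:
            raise ValueError("odd number of haplotypes; cannot pair into individuals")
        return self.hds[:, 0::2] + self.hds[:, 1::2]


def make_mask(n_markers: int, typed_indices: Sequence[int]) -> np.ndarray:
    """Boolean typed-marker mask from explicit indices."""
    mask = np.zeros(n_markers, dtype=bool)
    mask[np.asarray(typed_indices, dtype=int)] = True
    return mask


def _check_inputs(
    panel: HaplotypePanel, params: HMMParams, mask: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, bool]:
    M, H = panel.alleles.shape
    if M > MAX_MARKERS or H > MAX_HAPLOTYPES:
        raise ValueError(
            f"panel of {M} markers x {H} haplotypes exceeds the single-region "
            f"bound ({MAX_MARKERS} x {MAX_HAPLOTYPES}); window the input"
        )
    if params.n_markers != M:
        raise ValueError(f"params cover {params.n_markers} markers, panel has {M}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (M,):
        raise ValueError(f"mask shape {mask.shape} does not match {M} markers")
    if not mask.any():
        raise ValueError("mask has no typed markers")
    targets = np.asarray(targets)
    squeeze = targets.ndim == 1
    if squeeze:
        targets = targets[:, None]
    if targets.shape[0] != M:
        raise ValueError(f"target has {targets.shape[0]} markers, panel has {M}")
    targets = targets.astype(np.int8, copy=True)
    obs = targets[mask]
    if not np.isin(obs, (-1, 0, 1)).all():
        raise ValueError("target alleles must be 0, 1 or -1 (missing)")
    return targets, squeeze


def _run(
    alleles: np.ndarray,
    theta: np.ndarray,
    eps: np.ndarray,
    targets: np.ndarray,
    typed: np.ndarray,
    exclude_self: bool = False,
    want_post: bool = False,
    want_hds: bool = False,
    want_loo: bool = False,
    want_em: bool = False,
) -> dict:
    """Scaled forward-backward over a batch of targets.

    ``exclude_self=True`` pairs target column t with panel column t and
    removes that haplotype from its own copying panel (leave-one-out over
    the panel itself, used by EM estimation); requires T == H.

    Returns whatever was requested: posterior ``post`` (M,H,T), imputed
    ``hds`` (M,T), leave-one-out ``loo`` (M,T: at typed markers the dosage
    with the marker's own emission removed, elsewhere the ordinary dosage),
    EM statistics ``jump`` (M-1,) / ``mismatch`` (M,) summed over targets,
    and per-target log-likelihood ``loglik``.
    """
    M, H = alleles.shape
    T = targets.shape[1]
    heff = H - 1 if exclude_self else H
    if exclude_self and T != H:
        raise ValueError("exclude_self requires one target per panel haplotype")
    if heff < 1:
        raise ValueError("empty effective panel")

    out: dict = {"loglik": np.zeros(T)}
    if want_post:
        out["post"] = np.empty((M, H, T))
    if want_hds:
        out["hds"] = np.empty((M, T))
    if want_loo:
        out["loo"] = np.empty((M, T))
    if want_em:
        out["jump"] = np.zeros(max(M - 1, 0))
        out["mismatch"] = np.zeros(M)
        out["mismatch_weight"] = np.zeros(M)

    chunk = max(1, min(T, _CHUNK_BUDGET // (M * H)))
    af = alleles.astype(float)

    for lo in range(0, T, chunk):
        hi = min(lo + chunk, T)
        tc = targets[:, lo:hi]
        Tc = hi - lo
        if exclude_self:
            sel = np.ones((H, Tc), dtype=bool)
            sel[np.arange(lo, hi), np.arange(Tc)] = False
        else:
            sel = None

        def emission(m: int) -> np.ndarray | None:
            if not typed[m]:
                return None
            x = tc[m]
            e = np.where(alleles[m][:, None] == x[None, :], 1.0 - eps[m], eps[m])
            if (x < 0).any():
                e[:, x < 0] = 1.0
            return e

        # forward, stored
        F = np.empty((M, H, Tc))
        f = np.full((H, Tc), 1.0 / heff)
        if sel is not None:
            f = f * sel
        for m in range(M):
            if m > 0:
                f = (1.0 - theta[m - 1]) * f + theta[m - 1] / heff
                if sel is not None:
                    f = f * sel
            e = emission(m)
            if e is not None:
                f = f * e
            c = f.sum(axis=0)
            if (c <= 0).any():
                raise FloatingPointError("forward pass collapsed to zero mass")
            f = f / c
            out["loglik"][lo:hi] += np.log(c)
            F[m] = f
        # the log-likelihood picks up a constant from per-step uniform terms;
        # the scaling factors already absorb everything consistently.

        # backward sweep; b holds b_m = P(obs after m | state at m), rescaled
        b = np.ones((H, Tc))
        if sel is not None:
            b = b * sel
        for m in range(M - 1, -1, -1):
            g = F[m] * b
            g = g / g.sum(axis=0)
            if want_post:
                out["post"][m, :, lo:hi] = g
            if want_hds:
                out["hds"][m, lo:hi] = (g * af[m][:, None]).sum(axis=0)
            if want_em and typed[m]:
                x = tc[m]
                valid = x >= 0
                if valid.any():
                    mism = alleles[m][:, None] != x[None, :]
                    out["mismatch"][m] += (g[:, valid] * mism[:, valid]).sum()
                    out["mismatch_weight"][m] += int(valid.sum())
            if want_loo:
                if typed[m]:
                    if m == 0:
                        ft = np.full((H, Tc), 1.0 / heff)
                    else:
                        ft = (1.0 - theta[m - 1]) * F[m - 1] + theta[m - 1] / heff
                    if sel is not None:
                        ft = ft * sel
                    gl = ft * b
                    gl = gl / gl.sum(axis=0)
                    out["loo"][m, lo:hi] = (gl * af[m][:, None]).sum(axis=0)
                else:
                    out["loo"][m, lo:hi] = (g * af[m][:, None]).sum(axis=0)
            if m > 0:
                e = emission(m)
                u = b if e is None else e * b
                if want_em:
                    th = theta[m - 1]
                    su = u.sum(axis=0)
                    denom = ((1.0 - th) * F[m - 1] * u).sum(axis=0) + th / heff * su
                    out["jump"][m - 1] += float((th / heff * su / denom).sum())
                b = (1.0 - theta[m - 1]) * u + theta[m - 1] / heff * u.sum(axis=0)
                if sel is not None:
                    b = b * sel
                b = b / b.max(axis=0)
    return out


def forward_backward(
    target_alleles: Sequence[int],
    panel: HaplotypePanel,
    params: HMMParams,
    mask: np.ndarray,
) -> np.ndarray:
    """Posterior copying probabilities, markers x haplotypes (rows sum to 1).

    ``target_alleles`` is a full-length vector; entries at untyped markers
    are ignored and a -1 at a typed marker means missing (treated as untyped
    for this haplotype).  For a batch pass an (M, T) matrix; the result is
    then (M, H, T).
    """
    targets, squeeze = _check_inputs(panel, params, mask, np.asarray(target_alleles))
    res = _run(
        panel.alleles, params.theta, params.epsilon, targets,
        np.asarray(mask, dtype=bool), want_post=True,
    )
    post = res["post"]
    return post[:, :, 0] if squeeze else post


def impute(
    target_alleles: Sequence[int],
    panel: HaplotypePanel,
    params: HMMParams,
    mask: np.ndarray,
) -> DosageSet:
    """Impute haploid dosages: posterior-weighted panel alleles per marker."""
    targets, _ = _check_inputs(panel, params, mask, np.asarray(target_alleles))
    res = _run(
        panel.alleles, params.theta, params.epsilon, targets,
        np.asarray(mask, dtype=bool), want_hds=True,
    )
    return DosageSet(hds=res["hds"])


def loo_dosage(
    target_alleles: Sequence[int],
    panel: HaplotypePanel,
    params: HMMParams,
    mask: np.ndarray,
) -> np.ndarray:
    """Leave-one-out dosages: at each typed marker, the HDS recomputed with
    that marker's own emission removed (all other typed markers observed).

    Equivalent to re-running :func:`impute` once per typed marker with just
    that marker hidden, but computed in a single forward-backward sweep.
    Untyped markers carry the ordinary imputed dosage.  Shape (M,) or (M, T).
    """
    arr = np.asarray(target_alleles)
    targets, squeeze = _check_inputs(panel, params, mask, arr)
    res = _run(
        panel.alleles, params.theta, params.epsilon, targets,
        np.asarray(mask, dtype=bool), want_loo=True,
    )
    loo = np.clip(res["loo"], 0.0, 1.0)
    return loo[:, 0] if squeeze else loo
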