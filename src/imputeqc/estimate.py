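"""HMM parameter estimation and genetic-map conversion.

The switching rate theta is estimated from a reference panel by a
leave-one-haplotype-out Baum-Welch scheme: every panel haplotype in turn is
treated as a fully typed target and run against the remaining panel; the
posterior expected number of template re-draws per interval and mismatches
per marker give the M-step updates

    theta_i   = E[#jumps in interval i]   / H
    epsilon_j = E[#mismatches at marker j] / H

iterated to convergence.  This mirrors how Minimac-style software learns
panel-specific parameters: a large homogeneous panel offers long exact
matches (few expected switches, small theta), while ancestral diversity
shortens matches and drives theta up.

The genetic-map route converts centimorgan distance directly to a switching
rate with the convention that 0.01 cM corresponds to a 1% switching rate,
i.e. theta over an interval equals its cM length (clamped to (0, 1)).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .hmm import (
    EPSILON_CEIL,
    EPSILON_FLOOR,
    THETA_CEIL,
    THETA_FLOOR,
    HaplotypePanel,
    HMMParams,
    _run,
)

__all__ = [
    "EMConfig",
    "estimate_params",
    "total_theta",
    "GeneticMap",
    "theta_from_genetic_map",
    "write_params",
    "read_params",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EMConfig:
    """Settings for leave-one-haplotype-out EM.

    ``pooled=True`` estimates a single theta shared by all intervals (less
    noisy on small panels); per-interval is the default.  Initial values are
    fixed so estimation is reproducible.
    """

    max_iter: int = 20
    tol: float = 1e-4
    pooled: bool = False
    init_theta: float = 0.01
    init_epsilon: float = 1e-3
    estimate_epsilon: bool = True


def estimate_params(panel: HaplotypePanel, config: EMConfig | None = None) -> HMMParams:
    """Estimate per-interval theta and per-marker epsilon from a panel.

    Requires >= 3 haplotypes and >= 2 markers.  A degenerate panel (all
    haplotypes identical) carries no information about switching; it returns
    floor-clamped theta with a ``degenerate_panel`` diagnostic flag.
    """
    cfg = config or EMConfig()
    M, H = panel.alleles.shape
    if H < 3:
        raise ValueError(f"need at least 3 haplotypes to estimate, got {H}")
    if M < 2:
        raise ValueError(f"need at least 2 markers to estimate, got {M}")

    flags: list[str] = []
    if np.all(panel.alleles == panel.alleles[:, :1]):
        flags.append("degenerate_panel")
        return HMMParams(
            theta=np.full(M - 1, THETA_FLOOR),
            epsilon=np.full(M, cfg.init_epsilon),
            provenance="estimated",
            diagnostics={"flags": flags, "n_iter": 0, "converged": True, "loglik": []},
        )

    theta = np.full(M - 1, cfg.init_theta)
    eps = np.full(M, cfg.init_epsilon)
    typed = np.ones(M, dtype=bool)
    targets = panel.alleles.copy()
    logliks: list[float] = []
    converged = False
    n_iter = 0

    for it in range(cfg.max_iter):
        n_iter = it + 1
        res = _run(
            panel.alleles, theta, eps, targets, typed,
            exclude_self=True, want_em=True,
        )
        logliks.append(float(res["loglik"].sum()))
        if cfg.pooled:
            new_theta = np.full(M - 1, res["jump"].sum() / ((M - 1) * H))
        else:
            new_theta = res["jump"] / H
        new_theta = np.clip(new_theta, THETA_FLOOR, THETA_CEIL)
        if cfg.estimate_epsilon:
            w = np.maximum(res["mismatch_weight"], 1.0)
            new_eps = np.clip(res["mismatch"] / w, EPSILON_FLOOR, EPSILON_CEIL)
        else:
            new_eps = eps
        delta = max(
            float(np.max(np.abs(new_theta - theta) / np.maximum(theta, 1e-12))),
            float(np.max(np.abs(new_eps - eps) / np.maximum(eps, 1e-12))),
        )
        theta, eps = new_theta, new_eps
        if delta < cfg.tol:
            converged = True
            break

    return HMMParams(
        theta=theta,
        epsilon=eps,
        provenance="estimated" + ("_pooled" if cfg.pooled else ""),
        diagnostics={
            "flags": flags,
            "n_iter": n_iter,
            "converged": converged,
            "loglik": logliks,
        },
    )


def total_theta(params: HMMParams) -> float:
    """Sum of per-interval switching rates over the region.

    A panel-similarity summary: large homogeneous panels give small totals,
    diverse panels large ones.
    """
    return float(params.theta.sum())


@dataclasses.dataclass
class GeneticMap:
    """Ordered (position, cM) anchor points with linear interpolation.

    Positions off the grid are linearly extrapolated from the terminal
    segments (logged), falling back to constant extension for single-anchor
    maps.
    """

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.positions.size == 0:
            raise ValueError("genetic map is empty")
        if self.positions.shape != self.cm.shape or self.positions.ndim != 1:
            raise ValueError("positions and cM must be equal-length vectors")
        if not np.all(np.diff(self.positions) >= 0):
            raise ValueError("map positions must be non-decreasing")
        if not np.all(np.diff(self.cm) >= 0):
            raise ValueError("map cM values must be non-decreasing")

    @classmethod
    def from_file(cls, path: str) -> "GeneticMap":
        """Read a whitespace-delimited map.

        Three columns are (chrom, position, cM); four columns are taken as
        the PLINK .map dialect (chrom, id, cM, position).  Header lines that
        do not parse as numbers are skipped.
        """
        pos, cm = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                try:
                    if len(parts) >= 4:
                        p, c = int(parts[3]), float(parts[2])
                    elif len(parts) == 3:
                        p, c = int(parts[1]), float(parts[2])
                    else:
                        continue
                except ValueError:
                    continue  # header
                pos.append(p)
                cm.append(c)
        return cls(positions=np.array(pos), cm=np.array(cm))

    def interpolate(self, positions: Sequence[int]) -> np.ndarray:
        """cM coordinate at arbitrary base-pair positions."""
        q = np.asarray(positions, dtype=float)
        out = np.interp(q, self.positions.astype(float), self.cm)
        if self.positions.size >= 2:
            lo, hi = self.positions[0], self.positions[-1]
            below, above = q < lo, q > hi
            if below.any() or above.any():
                logger.info(
                    "extrapolating genetic map for %d positions outside [%d, %d]",
                    int(below.sum() + above.sum()), lo, hi,
                )
            if below.any():
                slope = self._edge_slope(0)
                out[below] = self.cm[0] + slope * (q[below] - lo)
            if above.any():
                slope = self._edge_slope(-1)
                out[above] = self.cm[-1] + slope * (q[above] - hi)
            np.maximum.accumulate(out, out=out)  # keep monotone after extrapolation
        return out

    def _edge_slope(self, end: int) -> float:
        if end == 0:
            dp = self.positions[1] - self.positions[0]
            dc = self.cm[1] - self.cm[0]
        else:
            dp = self.positions[-1] - self.positions[-2]
            dc = self.cm[-1] - self.cm[-2]
        return float(dc / dp) if dp > 0 else 0.0


def theta_from_genetic_map(
    gmap: GeneticMap,
    marker_positions: Sequence[int],
    epsilon: float = 1e-3,
) -> HMMParams:
    """Switching rates from map distance: theta = interval length in cM.

    Implements the 0.01 cM == 1% switching-rate convention, with floor/
    ceiling clamping; epsilon is set to a constant default.
    """
    pos = np.asarray(marker_positions, dtype=np.int64)
    if pos.ndim != 1 or pos.size < 1:
        raise ValueError("marker positions must be a nonempty vector")
    if not np.all(np.diff(pos) > 0):
        raise ValueError("marker positions must be strictly increasing")
    cm = gmap.interpolate(pos)
    theta = np.clip(np.diff(cm), THETA_FLOOR, THETA_CEIL)
    return HMMParams(
        theta=theta,
        epsilon=np.full(pos.size, epsilon),
        provenance="genetic_map",
    )


def write_params(params: HMMParams, variant_keys: Sequence[str], path: str) -> None:
    """Serialize params as a round-trippable tab-separated table.

    One row per marker: index, variant key, theta of the interval starting
    at this marker ("-" on the last row), epsilon at this marker.
    """
    if len(variant_keys) != params.n_markers:
        raise ValueError("variant keys do not match marker count")
    with open(path, "w") as fh:
        fh.write("#index\tvariant_key\ttheta\tepsilon\n")
        for i, key in enumerate(variant_keys):
            th = f"{params.theta[i]:.10g}" if i < params.theta.size else "-"
            fh.write(f"{i}\t{key}\t{th}\t{params.epsilon[i]:.10g}\n")


def read_params(path: str) -> tuple[HMMParams, list[str]]:
    """Inverse of :func:`write_params`; returns (params, variant keys)."""
    keys: list[str] = []
    theta: list[float] = []
    eps: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, key, th, ep = line.rstrip("\n").split("\t")
            keys.append(key)
            if th != "-":
                theta.append(float(th))
            eps.append(float(ep))
    if len(theta) != len(eps) - 1:
        raise ValueError("malformed params table")
    return (
        HMMParams(theta=np.array(theta), epsilon=np.array(eps), provenance="manual"),
        keys,
    )
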