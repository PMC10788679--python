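"""Synthetic multi-ancestry reference panels with tunable divergence and LD.

Ancestral divergence follows the Balding-Nichols model: each ancestry's
per-marker allele frequency is drawn around a shared base frequency p from
Beta(p(1-F)/F, (1-p)(1-F)/F), so E[freq] = p and Var[freq] = F p(1-p) with F
the fixation index (FST).  Linkage disequilibrium is created by a founder-
mosaic process: a small set of founder haplotypes is drawn independently per
marker from the ancestry frequencies, and every panel/target haplotype is a
mosaic of founders that re-draws its founder uniformly with a per-interval
copy rate, plus a small per-marker mutation (allele flip) rate.  This is the
same copying process the imputation HMM assumes, with the copy rate playing
the role of the switching rate.

Everything is deterministic given the PanelSpec seed; sub-streams are
derived per ancestry and per role so panels, targets and masks are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm import HaplotypePanel, make_mask

__all__ = [
    "AncestrySpec",
    "PanelSpec",
    "SimulatedData",
    "draw_ancestry_freqs",
    "simulate_haplotypes",
    "build_panel",
    "mask_array",
    "standard_benchmark_spec",
    "simulate_targets_from_panel",
]

_NUCS = np.array(list("ACGT"))


@dataclasses.dataclass
class AncestrySpec:
    """One ancestry block: size, divergence from the base, founder count."""

    label: str
    n_haplotypes: int
    fst: float = 0.0
    n_founders: int = 20
    n_targets: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1 or self.n_founders < 1:
            raise ValueError("haplotype and founder counts must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.n_targets < 0:
            raise ValueError("n_targets must be nonnegative")


@dataclasses.dataclass
class PanelSpec:
    """Recipe for a simulated panel; fully determined by its seed."""

    n_markers: int
    ancestries: list[AncestrySpec]
    f_lo: float = 0.02
    f_hi: float = 0.98
    copy_rate: float = 0.02
    mutation_rate: float = 1e-3
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")
        if not self.ancestries:
            raise ValueError("need at least one ancestry")
        total = sum(a.n_haplotypes for a in self.ancestries)
        if total < 2:
            raise ValueError("total panel haplotypes must be >= 2")
        if not 0.0 < self.copy_rate < 1.0:
            raise ValueError("copy_rate must be in (0, 1)")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5)")
        if not 0.0 < self.f_lo < self.f_hi < 1.0:
            raise ValueError("base frequency bounds must satisfy 0 < lo < hi < 1")


@dataclasses.dataclass
class SimulatedData:
    """A built panel plus held-out truth-known targets and bookkeeping."""

    panel: HaplotypePanel
    targets: HaplotypePanel | None
    spec: PanelSpec
    base_freqs: np.ndarray
    ancestry_freqs: dict[str, np.ndarray]


def draw_ancestry_freqs(
    base_freqs: Sequence[float], fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols draw of per-ancestry frequencies around the base."""
    p = np.asarray(base_freqs, dtype=float)
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("base frequencies must lie in (0, 1)")
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_haplotypes(
    founders: np.ndarray,
    copy_rate: float,
    mutation_rate: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder-mosaic haplotypes: (markers x n) 0/1 matrix.

    Each haplotype copies a founder, re-drawing the founder uniformly (self
    included) between adjacent markers with probability ``copy_rate``; the
    copied allele is flipped with probability ``mutation_rate``.
    """
    founders = np.asarray(founders)
    if founders.ndim != 2 or founders.shape[1] < 1:
        raise ValueError("founders must be a markers x founders matrix")
    if n < 1:
        raise ValueError("n must be >= 1")
    M, K = founders.shape
    drawn = rng.integers(0, K, size=(M, n))
    switch = rng.random((M, n)) < copy_rate
    switch[0, :] = True
    row = np.where(switch, np.arange(M)[:, None], 0)
    last = np.maximum.accumulate(row, axis=0)
    idx = drawn[last, np.arange(n)[None, :]]
    haps = founders[np.arange(M)[:, None], idx].astype(np.int8)
    if mutation_rate > 0:
        flips = rng.random((M, n)) < mutation_rate
        haps = np.where(flips, 1 - haps, haps).astype(np.int8)
    return haps


def _markers_frame(spec: PanelSpec, rng: np.random.Generator) -> pd.DataFrame:
    pos = 1 + 1000 * np.arange(spec.n_markers, dtype=np.int64)
    ref_idx = rng.integers(0, 4, size=spec.n_markers)
    alt_idx = (ref_idx + rng.integers(1, 4, size=spec.n_markers)) % 4
    return pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos": pos,
            "id": [f"sim{i}" for i in range(spec.n_markers)],
            "ref": _NUCS[ref_idx],
            "alt": _NUCS[alt_idx],
        }
    )


def build_panel(spec: PanelSpec) -> SimulatedData:
    """Generate the panel and held-out targets described by ``spec``.

    Targets are generated from the same founders/process as their ancestry
    block but are excluded from the panel.  Monomorphic markers (across the
    combined panel) are flagged in ``panel.markers['monomorphic']`` so that
    metric evaluation can exclude them downstream.
    """
    root = np.random.SeedSequence(spec.seed)
    s_base, s_markers, *s_anc = root.spawn(2 + len(spec.ancestries))
    rng_base = np.random.default_rng(s_base)
    base = rng_base.uniform(spec.f_lo, spec.f_hi, size=spec.n_markers)
    markers = _markers_frame(spec, np.random.default_rng(s_markers))

    blocks, tblocks, labels, tlabels = [], [], [], []
    anc_freqs: dict[str, np.ndarray] = {}
    for anc, ss in zip(spec.ancestries, s_anc):
        s_freq, s_found, s_hap, s_tgt = ss.spawn(4)
        freqs = draw_ancestry_freqs(base, anc.fst, np.random.default_rng(s_freq))
        anc_freqs[anc.label] = freqs
        rng_f = np.random.default_rng(s_found)
        founders = (
            rng_f.random((spec.n_markers, anc.n_founders)) < freqs[:, None]
        ).astype(np.int8)
        blocks.append(
            simulate_haplotypes(
                founders, spec.copy_rate, spec.mutation_rate,
                anc.n_haplotypes, np.random.default_rng(s_hap),
            )
        )
        labels.extend([anc.label] * anc.n_haplotypes)
        if anc.n_targets:
            tblocks.append(
                simulate_haplotypes(
                    founders, spec.copy_rate, spec.mutation_rate,
                    anc.n_targets, np.random.default_rng(s_tgt),
                )
            )
            tlabels.extend([anc.label] * anc.n_targets)

    alleles = np.hstack(blocks)
    pm = markers.copy()
    counts = alleles.sum(axis=1)
    pm["monomorphic"] = (counts == 0) | (counts == alleles.shape[1])
    panel = HaplotypePanel(alleles=alleles, markers=pm, ancestry=np.array(labels))

    if tblocks:
        targets = HaplotypePanel(
            alleles=np.hstack(tblocks),
            markers=markers.copy(),
            ancestry=np.array(tlabels),
        )
    else:
        targets = None
    return SimulatedData(
        panel=panel, targets=targets, spec=spec, base_freqs=base, ancestry_freqs=anc_freqs
    )


def mask_array(
    n_markers: int,
    typed_fraction: float | None = None,
    typed_indices: Sequence[int] | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random typed-marker mask emulating a genotyping array scaffold.

    Exactly ``round(typed_fraction * n_markers)`` markers are typed, chosen
    uniformly at random, with both endpoint markers forced typed so that
    untyped sites are always interpolations between observed ones.  An
    explicit index list bypasses the random choice.
    """
    if typed_indices is not None:
        return make_mask(n_markers, typed_indices)
    if typed_fraction is None or not 0.0 < typed_fraction < 1.0:
        raise ValueError("typed_fraction must be in (0, 1)")
    k = int(round(typed_fraction * n_markers))
    if k < 2:
        raise ValueError(f"typed fraction {typed_fraction} yields fewer than 2 typed markers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    middle = rng.choice(np.arange(1, n_markers - 1), size=k - 2, replace=False)
    mask = np.zeros(n_markers, dtype=bool)
    mask[[0, n_markers - 1]] = True
    mask[middle] = True
    return mask


def standard_benchmark_spec(seed: int = 20240113) -> PanelSpec:
    """The standard synthetic benchmark used across modules and experiments:
    two ancestries at FST 0.1, 150+150 panel haplotypes, 1000 markers, 20
    founders each, copy rate 0.02, mutation 1e-3, 30+30 target haplotypes.
    """
    return PanelSpec(
        n_markers=1000,
        ancestries=[
            AncestrySpec("ANC_A", 150, fst=0.1, n_founders=20, n_targets=30),
            AncestrySpec("ANC_B", 150, fst=0.1, n_founders=20, n_targets=30),
        ],
        copy_rate=0.02,
        mutation_rate=1e-3,
        seed=seed,
    )


def simulate_targets_from_panel(
    panel: HaplotypePanel,
    n: int,
    copy_rate: float,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Targets generated by copying the panel haplotypes themselves.

    When imputed with theta = copy_rate and epsilon = mutation_rate, the HMM
    posterior is the exact conditional of this generative process, i.e. the
    well-calibrated setting in which Rsq matches dosage r2 in expectation.
    """
    return simulate_haplotypes(panel.alleles, copy_rate, mutation_rate, n, rng)
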