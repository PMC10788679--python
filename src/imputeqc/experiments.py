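"""Evaluation procedures: theta scaling, panel composition, binning, counts.

These orchestrate the library into the two study designs the package exists
to demonstrate:

* ``run_theta_scaling`` imputes a fixed target set against a fixed panel
  while multiplying every interval's switching rate by a grid of folds.
  Down-scaling theta concentrates the copying posterior on few templates,
  pushing haploid dosages toward 0/1 (more "confident alleles"), inflating
  Var(dosage) and hence Rsq, while the squared correlation with truth
  (EmpRsq / dosage r2) barely moves -- so the deviation Rsq - EmpRsq swings
  from positive (low theta) to negative (high theta).

* ``run_panel_composition`` re-estimates theta for panels of different sizes
  and ancestry mixes and measures the downstream metrics, reproducing the
  size/diversity trade-off: theta falls with single-ancestry panel size and
  rises with ancestral diversity.

Accuracy is evaluated leave-one-out at typed markers (the array scaffold)
and against held-out truth at untyped markers.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .estimate import EMConfig, estimate_params, total_theta
from .hmm import HaplotypePanel, HMMParams, impute, loo_dosage, scale_theta
from .metrics import MetricRecord, decompose_matrix, records_to_frame
from .simulate import PanelSpec, build_panel, mask_array

__all__ = [
    "DEFAULT_FOLDS",
    "FOLD_GRID_21",
    "maf_bin",
    "count_confident_alleles",
    "count_high_rsq",
    "bin_and_bootstrap",
    "evaluate_fold",
    "run_theta_scaling",
    "CompositionScenario",
    "run_panel_composition",
    "ancestry_specific_variants",
    "total_theta_replicates",
    "ExperimentResult",
]

DEFAULT_FOLDS = (0.01, 0.1, 0.5, 1.0, 2.0, 10.0, 100.0)
#: the full scaling grid, 21 logarithmically spaced folds spanning 0.01-100
FOLD_GRID_21 = tuple(np.round(np.logspace(-2, 2, 21), 6))

MAF_BIN_ORDER = ["common", "low_frequency", "rare", "doubleton", "singleton", "other"]


def maf_bin(maf: float, mac: int, n: int | None = None) -> str:
    """Frequency bin label; MAC rules take precedence for MAC <= 2.

    common: MAF >= 5%; low_frequency: 0.5% <= MAF < 5%;
    rare: 0.1% < MAF < 0.5%; doubleton: MAC == 2; singleton: MAC == 1.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    if mac < 0:
        raise ValueError("mac must be nonnegative")
    if n is not None and abs(maf * n - mac) > 0.5 + 1e-9:
        raise ValueError(f"inconsistent maf={maf}, mac={mac} for n={n}")
    if mac == 1:
        return "singleton"
    if mac == 2:
        return "doubleton"
    if maf >= 0.05:
        return "common"
    if maf >= 0.005:
        return "low_frequency"
    if maf > 0.001:
        return "rare"
    return "other"


def count_confident_alleles(hds: np.ndarray, threshold: float = 0.9) -> int:
    """Number of imputed alleles with HDS strictly above the threshold."""
    hds = np.asarray(hds, dtype=float)
    if hds.size == 0:
        return 0
    if hds.min() < 0 or hds.max() > 1:
        raise ValueError("hds entries must lie in [0, 1]")
    return int((hds > threshold).sum())


def count_high_rsq(
    records: Sequence[MetricRecord], threshold: float = 0.7
) -> tuple[int, int]:
    """(count of variants with Rsq strictly above threshold, count excluded).

    Records with a missing Rsq are excluded from the comparison and tallied
    in the second element.  ``threshold=0.3`` implements the conventional
    global Rsq filter.
    """
    count = 0
    excluded = 0
    for r in records:
        if np.isnan(r.rsq):
            excluded += 1
        elif r.rsq > threshold:
            count += 1
    return count, excluded


def bin_and_bootstrap(
    frame: pd.DataFrame,
    bin_metric: str = "emprsq",
    width: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean deviation Rsq - EmpRsq per metric bin, with bootstrap 95% CI.

    Variants are grouped into [k*width, (k+1)*width) bins of ``bin_metric``
    (either axis of the deviation diagnostic: "emprsq" bins for the raw
    deviation, "rsq" bins for MARE-style summaries); within each bin the
    variants are resampled with replacement ``n_boot`` times and the 2.5%
    and 97.5% empirical quantiles of the resampled bin-mean deviation are
    reported.  Deterministic given the seed.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    df = frame.dropna(subset=["rsq", "emprsq"]).copy()
    if df.empty:
        raise ValueError("no records with both Rsq and EmpRsq defined")
    rng = np.random.default_rng(seed)
    df["_dev"] = df["rsq"] - df["emprsq"]
    df["_bin"] = np.floor(df[bin_metric] / width).astype(int)
    rows = []
    for k, grp in df.groupby("_bin", sort=True):
        dev = grp["_dev"].to_numpy()
        boots = rng.choice(dev, size=(n_boot, dev.size), replace=True).mean(axis=1)
        lo, hi = np.quantile(boots, [0.025, 0.975])
        mean = float(dev.mean())
        rows.append(
            {
                "bin_metric": bin_metric,
                "lower": k * width,
                "upper": (k + 1) * width,
                "n": int(dev.size),
                "mean_dev": mean,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "bracketed": bool(lo <= mean <= hi),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ExperimentResult:
    """Per-condition summary tables plus the exact seeds/config used."""

    summary: pd.DataFrame
    by_maf: pd.DataFrame
    per_variant: dict[str, pd.DataFrame]
    config: dict


def _maf_labels(truth: np.ndarray) -> list[str]:
    n = truth.shape[1]
    ac = truth.sum(axis=1)
    mac = np.minimum(ac, n - ac).astype(int)
    maf = mac / n
    return [maf_bin(float(f), int(c), n) for f, c in zip(maf, mac)]


def evaluate_fold(
    panel: HaplotypePanel,
    truth: np.ndarray,
    mask: np.ndarray,
    params: HMMParams,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Impute + decompose one parameter setting.

    Returns (per-variant metric frame, evaluation dosage matrix).  Typed
    markers are scored leave-one-out; untyped markers against held-out
    truth.  Variants monomorphic in the truth are flagged by decompose and
    excluded from summaries downstream.
    """
    obs = np.where(mask[:, None], truth, -1).astype(np.int8)
    loo = loo_dosage(obs, panel, params, mask)
    full = impute(obs, panel, params, mask).hds
    y_eval = np.where(mask[:, None], loo, full)
    keys = panel.variant_keys()
    records = decompose_matrix(truth, y_eval, variant_keys=keys)
    df = records_to_frame(records)
    df["typed"] = mask
    df["maf_bin"] = _maf_labels(truth)
    df["_records"] = records
    return df, y_eval


def _summarize(df: pd.DataFrame, y_eval: np.ndarray, label: dict) -> tuple[dict, pd.DataFrame]:
    ok = df[df["flags"] == "ok"]
    records = list(df["_records"])
    high, excluded = count_high_rsq([r for r in records if r.ok])
    row = {
        **label,
        "n_variants": int(len(df)),
        "n_ok": int(len(ok)),
        "mean_rsq": float(ok["rsq"].mean()),
        "mean_emprsq": float(ok["emprsq"].mean()),
        "mean_mare": float(ok["mare"].mean()),
        "mean_beta_imp": float(ok["beta_imp"].mean()),
        "mean_dev": float((ok["rsq"] - ok["emprsq"]).mean()),
        "confident_alleles": count_confident_alleles(y_eval),
        "high_rsq": high,
        "n_flagged": int(len(df) - len(ok)) + excluded,
    }
    by = (
        ok.groupby("maf_bin")
        .agg(
            n=("rsq", "size"),
            mean_rsq=("rsq", "mean"),
            mean_emprsq=("emprsq", "mean"),
            mean_mare=("mare", "mean"),
            mean_beta_imp=("beta_imp", "mean"),
        )
        .reset_index()
    )
    for k, v in label.items():
        by[k] = v
    return row, by


def run_theta_scaling(
    panel: HaplotypePanel,
    targets: HaplotypePanel,
    mask: np.ndarray,
    params: HMMParams,
    folds: Sequence[float] = DEFAULT_FOLDS,
    seed: int = 0,
) -> ExperimentResult:
    """Impute the targets under each theta scaling fold and summarize.

    For every fold the interval switching rates are multiplied (clamped),
    the targets re-imputed, and per-variant metrics decomposed; summaries
    include MAF-stratified means, confident-allele (HDS > 0.9) and high-Rsq
    (Rsq > 0.7) counts.
    """
    if not len(folds) or any(f <= 0 for f in folds):
        raise ValueError("folds must be positive")
    truth = targets.alleles
    rows, maf_tables, per_variant = [], [], {}
    for fold in folds:
        df, y_eval = evaluate_fold(panel, truth, mask, scale_theta(params, fold))
        row, by = _summarize(df, y_eval, {"fold": fold})
        rows.append(row)
        maf_tables.append(by)
        per_variant[str(fold)] = df.drop(columns="_records")
    return ExperimentResult(
        summary=pd.DataFrame(rows),
        by_maf=pd.concat(maf_tables, ignore_index=True),
        per_variant=per_variant,
        config={
            "experiment": "theta_scaling",
            "folds": list(folds),
            "seed": seed,
            "n_panel_haplotypes": panel.n_haplotypes,
            "n_targets": truth.shape[1],
            "n_markers": panel.n_markers,
        },
    )


def ancestry_specific_variants(panel: HaplotypePanel) -> pd.Series:
    """Label variants whose alternate allele occurs in exactly one ancestry
    block ("<label>_only"), in several ("shared") or nowhere ("absent")."""
    if panel.ancestry is None:
        raise ValueError("panel has no ancestry labels")
    labels = pd.unique(panel.ancestry)
    present = {
        lab: panel.alleles[:, panel.ancestry == lab].sum(axis=1) > 0 for lab in labels
    }
    n_present = np.sum([present[lab] for lab in labels], axis=0)
    out = np.where(n_present == 0, "absent", "shared").astype(object)
    for lab in labels:
        only = present[lab] & (n_present == 1)
        out[only] = f"{lab}_only"
    return pd.Series(out, name="ancestry_specific")


@dataclasses.dataclass
class CompositionScenario:
    """One panel composition: a simulation spec plus the target ancestry."""

    name: str
    spec: PanelSpec
    target_ancestry: str
    typed_fraction: float = 0.25


def run_panel_composition(
    scenarios: Sequence[CompositionScenario],
    seed: int = 0,
    em_config: EMConfig | None = None,
    params_override: HMMParams | None = None,
) -> ExperimentResult:
    """Estimate theta and evaluate imputation for each panel composition.

    For each scenario: build the panel, estimate HMM parameters from it
    (unless ``params_override`` pins them, emulating a parameter set fixed
    from a different panel), impute the held-out targets of the named
    ancestry, decompose metrics, and count confident alleles / high-Rsq
    variants overall and restricted to ancestry-specific variants.
    """
    rows, maf_tables, per_variant = [], [], {}
    for sc in scenarios:
        sim = build_panel(sc.spec)
        if sim.targets is None:
            raise ValueError(f"scenario {sc.name!r} generated no targets")
        tmask = sim.targets.ancestry == sc.target_ancestry
        if not tmask.any():
            raise ValueError(
                f"scenario {sc.name!r} has no targets of ancestry {sc.target_ancestry!r}"
            )
        truth = sim.targets.alleles[:, tmask]
        mask = mask_array(
            sc.spec.n_markers,
            typed_fraction=sc.typed_fraction,
            seed=np.random.default_rng(np.random.SeedSequence((seed, sc.spec.seed))),
        )
        params = params_override or estimate_params(sim.panel, em_config)
        df, y_eval = evaluate_fold(sim.panel, truth, mask, params)
        row, by = _summarize(df, y_eval, {"scenario": sc.name})
        row["total_theta"] = total_theta(params)
        row["target_ancestry"] = sc.target_ancestry
        if len(pd.unique(sim.panel.ancestry)) > 1:
            spec_labels = ancestry_specific_variants(sim.panel)
            df = df.assign(ancestry_specific=spec_labels.values)
            for lab in pd.unique(sim.panel.ancestry):
                only = spec_labels == f"{lab}_only"
                sub = [r for r, keep in zip(df["_records"], only) if keep and r.ok]
                row[f"high_rsq_{lab}_only"], _ = count_high_rsq(sub)
                row[f"confident_alleles_{lab}_only"] = count_confident_alleles(
                    y_eval[only.to_numpy()]
                )
        rows.append(row)
        maf_tables.append(by)
        per_variant[sc.name] = df.drop(columns="_records")
    return ExperimentResult(
        summary=pd.DataFrame(rows),
        by_maf=pd.concat(maf_tables, ignore_index=True),
        per_variant=per_variant,
        config={
            "experiment": "panel_composition",
            "scenarios": [sc.name for sc in scenarios],
            "seed": seed,
        },
    )


def total_theta_replicates(
    spec: PanelSpec,
    panel_size: int,
    n_replicates: int = 10,
    seed: int = 0,
    em_config: EMConfig | None = None,
) -> list[float]:
    """Total theta across replicate subpanels of a fixed size.

    A pool of haplotypes is generated once from ``spec``; each replicate
    draws a fresh random subset of ``panel_size`` haplotypes (preserving the
    pool's ancestry proportions) and re-estimates the parameters.  This is
    the subsample-and-reestimate protocol used to study how panel size and
    diversity shape the switching-rate estimates.
    """
    sim = build_panel(spec)
    pool = sim.panel
    if panel_size > pool.n_haplotypes:
        raise ValueError("panel_size exceeds the generated pool")
    labels = pd.unique(pool.ancestry)
    per_anc = {
        lab: np.flatnonzero(pool.ancestry == lab) for lab in labels
    }
    totals = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, spec.seed, rep)))
        take = []
        for lab in labels:
            k = int(round(panel_size * len(per_anc[lab]) / pool.n_haplotypes))
            take.append(rng.choice(per_anc[lab], size=k, replace=False))
        idx = np.sort(np.concatenate(take))
        params = estimate_params(pool.take_haplotypes(idx), em_config)
        totals.append(total_theta(params))
    return totals
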