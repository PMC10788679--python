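"""VCF and table I/O.

Reading goes through pysam; writing is plain VCF 4.2 text so the printed
precision of the dosage fields is exactly specified (DS and each HDS entry
with 3 decimals).  Scope is strict: biallelic SNVs with fully phased GT;
anything else is rejected with a position-identified error rather than
partially loaded.  Plain and gzipped VCF are both accepted.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
import pysam

from .hmm import DosageSet, HaplotypePanel
from .metrics import MetricRecord

__all__ = [
    "VCFFormatError",
    "read_panel",
    "write_panel",
    "write_dosages",
    "read_dosages",
    "write_info_table",
    "info_table_frame",
]

INFO_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "AAF", "MAF",
    "Rsq", "EmpRsq", "MARE", "BetaImp", "N", "FLAGS",
]


class VCFFormatError(ValueError):
    """Malformed or out-of-scope VCF content, with the offending position."""


def _where(rec) -> str:
    return f"{rec.chrom}:{rec.pos}"


def read_panel(path: str, allow_missing: bool = False) -> HaplotypePanel:
    """Load a phased VCF as a haplotype matrix (2 columns per sample).

    ``allow_missing=True`` admits missing alleles (encoded -1), for target
    files; panel mode requires complete data.  Multiallelic, unphased,
    non-SNV, duplicated or unsorted records are rejected.
    """
    rows: list[list[int]] = []
    meta: dict[str, list] = {"chrom": [], "pos": [], "id": [], "ref": [], "alt": []}
    seen: set[tuple] = set()
    last: tuple[str, int] | None = None
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise VCFFormatError("VCF has no samples")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise VCFFormatError(
                    f"multiallelic record at {_where(rec)}; split into biallelic "
                    "records first (e.g. bcftools norm -m -)"
                )
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise VCFFormatError(f"non-SNV record at {_where(rec)}")
            key = (rec.chrom, rec.pos, ref, alt)
            if key in seen:
                raise VCFFormatError(f"duplicate variant at {_where(rec)}")
            seen.add(key)
            if last is not None and rec.chrom == last[0] and rec.pos <= last[1]:
                raise VCFFormatError(f"positions not sorted at {_where(rec)}")
            last = (rec.chrom, rec.pos)
            row: list[int] = []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    if not allow_missing:
                        raise VCFFormatError(f"missing GT at {_where(rec)} sample {s}")
                    row.extend([-1, -1])
                    continue
                if len(gt) == 2 and not call.phased:
                    raise VCFFormatError(
                        f"unphased genotype at {_where(rec)} sample {s}; "
                        "panel/target haplotypes must be phased ('|')"
                    )
                for a in gt:
                    if a is None:
                        if not allow_missing:
                            raise VCFFormatError(
                                f"missing allele at {_where(rec)} sample {s}"
                            )
                        row.append(-1)
                    elif a in (0, 1):
                        row.append(a)
                    else:
                        raise VCFFormatError(f"allele out of range at {_where(rec)}")
                if len(gt) == 1:
                    row.append(row[-1])  # haploid record: duplicate the allele
            rows.append(row)
            meta["chrom"].append(rec.chrom)
            meta["pos"].append(rec.pos)
            meta["id"].append(rec.id or ".")
            meta["ref"].append(ref)
            meta["alt"].append(alt)
    if not rows:
        raise VCFFormatError("VCF contains no usable records")
    alleles = np.asarray(rows, dtype=np.int8)
    markers = pd.DataFrame(meta)
    if allow_missing:
        panel = HaplotypePanel.__new__(HaplotypePanel)
        panel.alleles = alleles
        panel.markers = markers
        panel.ancestry = None
        return panel
    return HaplotypePanel(alleles=alleles, markers=markers)


def _open_out(path: str) -> TextIO:
    if str(path).endswith(".gz"):
        # BGZF so that htslib/pysam can read the file back
        import io

        return io.TextIOWrapper(pysam.BGZFile(path, "wb"))
    return open(path, "w")


def _header(chroms: Sequence[str], samples: Sequence[str], fmt: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=imputeqc"]
    for c in dict.fromkeys(chroms):
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if "DS" in fmt:
        lines.append(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Diploid alternate allele dosage">'
        )
    if "HDS" in fmt:
        lines.append(
            '##FORMAT=<ID=HDS,Number=.,Type=Float,Description="Haploid alternate allele dosages">'
        )
    head = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    return "\n".join(lines) + "\n" + head + "\t" + "\t".join(samples) + "\n"


def write_panel(
    panel: HaplotypePanel, path: str, sample_names: Sequence[str] | None = None
) -> None:
    """Write a haplotype matrix as a phased GT-only VCF (2 haplotypes/sample)."""
    M, H = panel.alleles.shape
    if H % 2:
        raise ValueError("odd haplotype count; cannot pair into diploid samples")
    n_samples = H // 2
    if sample_names is None:
        sample_names = [f"S{i}" for i in range(n_samples)]
    if len(sample_names) != n_samples:
        raise ValueError("sample name count does not match haplotype pairs")
    m = panel.markers
    with _open_out(path) as fh:
        fh.write(_header(list(m["chrom"]), sample_names, "GT"))
        ids = m["id"] if "id" in m.columns else ["."] * M
        for i in range(M):
            a = panel.alleles[i]
            gts = "\t".join(f"{a[2*s]}|{a[2*s+1]}" for s in range(n_samples))
            fh.write(
                f"{m['chrom'].iloc[i]}\t{m['pos'].iloc[i]}\t{ids.iloc[i] if hasattr(ids, 'iloc') else ids[i]}\t"
                f"{m['ref'].iloc[i]}\t{m['alt'].iloc[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dosages(
    dosages: DosageSet,
    markers: pd.DataFrame,
    path: str,
    sample_names: Sequence[str] | None = None,
) -> None:
    """Write imputed dosages as VCF with FORMAT GT:DS:HDS.

    HDS is the pair of per-haplotype dosages, 3 decimals, comma-joined; DS
    their sum; GT the hard-call (HDS > 0.5 -> alt), phased.
    """
    hds = dosages.hds
    M, H = hds.shape
    if H % 2:
        raise ValueError("odd haplotype count; cannot pair into diploid samples")
    if len(markers) != M:
        raise ValueError("marker table does not match dosage matrix")
    n_samples = H // 2
    if sample_names is None:
        sample_names = [f"S{i}" for i in range(n_samples)]
    if len(sample_names) != n_samples:
        raise ValueError("sample name count does not match haplotype pairs")
    with _open_out(path) as fh:
        fh.write(_header(list(markers["chrom"]), sample_names, "GT:DS:HDS"))
        ids = markers["id"] if "id" in markers.columns else pd.Series(["."] * M)
        for i in range(M):
            cells = []
            for s in range(n_samples):
                h1, h2 = hds[i, 2 * s], hds[i, 2 * s + 1]
                gt = f"{int(h1 > 0.5)}|{int(h2 > 0.5)}"
                cells.append(f"{gt}:{h1 + h2:.3f}:{h1:.3f},{h2:.3f}")
            fh.write(
                f"{markers['chrom'].iloc[i]}\t{markers['pos'].iloc[i]}\t{ids.iloc[i]}\t"
                f"{markers['ref'].iloc[i]}\t{markers['alt'].iloc[i]}\t.\tPASS\t.\t"
                "GT:DS:HDS\t" + "\t".join(cells) + "\n"
            )


def read_dosages(path: str) -> tuple[DosageSet, pd.DataFrame, list[str]]:
    """Read a GT:DS:HDS VCF back into (dosages, markers, sample names).

    Checks the DS = sum(HDS) consistency contract at printed precision.
    """
    rows: list[list[float]] = []
    meta: dict[str, list] = {"chrom": [], "pos": [], "id": [], "ref": [], "alt": []}
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise VCFFormatError(f"multiallelic record at {_where(rec)}")
            row: list[float] = []
            for s in samples:
                call = rec.samples[s]
                hds = call.get("HDS")
                if hds is None:
                    raise VCFFormatError(f"missing HDS at {_where(rec)} sample {s}")
                hds = [float(v) for v in hds]
                if len(hds) != 2:
                    raise VCFFormatError(f"HDS is not a haplotype pair at {_where(rec)}")
                if any(v < 0 or v > 1 for v in hds):
                    raise VCFFormatError(f"HDS out of [0,1] at {_where(rec)}")
                ds = call.get("DS")
                if ds is not None and not math.isclose(
                    float(ds), sum(hds), abs_tol=2e-3
                ):
                    raise VCFFormatError(f"DS != sum(HDS) at {_where(rec)} sample {s}")
                row.extend(hds)
            rows.append(row)
            meta["chrom"].append(rec.chrom)
            meta["pos"].append(rec.pos)
            meta["id"].append(rec.id or ".")
            meta["ref"].append(rec.ref)
            meta["alt"].append(rec.alts[0])
    if not rows:
        raise VCFFormatError("VCF contains no usable records")
    return DosageSet(hds=np.asarray(rows)), pd.DataFrame(meta), samples


def _fmt(v: float) -> str:
    return "-" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.6g}"


def info_table_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Per-variant Minimac-style info table as a DataFrame.

    Variant keys are parsed as chrom:pos:ref:alt; missing metrics become
    "-"; MAF is min(AAF, 1-AAF).
    """
    rows = []
    for r in records:
        parts = str(r.variant_key).split(":")
        chrom, pos, ref, alt = (parts + ["-"] * 4)[:4] if len(parts) >= 4 else (
            str(r.variant_key), "-", "-", "-",
        )
        rows.append(
            {
                "CHROM": chrom,
                "POS": pos,
                "REF": ref,
                "ALT": alt,
                "AAF": _fmt(r.p),
                "MAF": _fmt(r.maf),
                "Rsq": _fmt(r.rsq),
                "EmpRsq": _fmt(r.emprsq),
                "MARE": _fmt(r.mare),
                "BetaImp": _fmt(r.beta_imp),
                "N": r.n_haplotypes,
                "FLAGS": ",".join(r.flags),
            }
        )
    return pd.DataFrame(rows, columns=INFO_COLUMNS)


def write_info_table(records: Iterable[MetricRecord], path: str) -> None:
    """Write the tab-separated per-variant metric table."""
    info_table_frame(records).to_csv(path, sep="\t", index=False)
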