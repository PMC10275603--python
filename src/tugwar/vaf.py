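"""Variant read-count tables, coverage equalization, and synthetic pairs.

Paired tumor samples (e.g. a primary tumor and its lymph-node metastasis)
are sequenced at different depths, which biases the comparison of their
variant-allele-frequency spectra.  The total-count histogram equalization
implemented here resamples each sample so that their per-bin total-read
histograms match exactly:

1. build total-read histograms for both samples with a common bin width;
2. per bin, take the lower of the two counts as the target;
3. sort variants by total reads and partition them into the bins;
4. per bin, prune the larger subset by uniform random choice without
   replacement down to the target.

The synthetic paired-table generator stands in for controlled-access
patient data: given underlying site frequencies (from simulation or a
theoretical spectrum), it draws per-site depths from an over-dispersed
negative-binomial model and variant reads binomially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import CumulativeTail

__all__ = [
    "VariantTable",
    "read_variants",
    "write_variants",
    "histogram_equalize",
    "freedman_diaconis_width",
    "synthesize_paired_tables",
    "compare_tails",
]

logger = logging.getLogger(__name__)

_COLUMNS = ["site", "total_reads", "variant_reads"]


@dataclass
class VariantTable:
    """Per-site read counts for one sequenced sample."""

    df: pd.DataFrame
    sample: str = "sample"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")
        self.df = self.df[_COLUMNS].reset_index(drop=True)
        if (self.df["total_reads"] < 0).any() or (self.df["variant_reads"] < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.df["variant_reads"] > self.df["total_reads"]).any():
            raise ValueError("variant_reads exceeds total_reads")
        if self.df["site"].duplicated().any():
            raise ValueError("site ids must be unique within a sample")

    def __len__(self) -> int:
        return len(self.df)


def read_variants(path: str | Path, format: str | None = None, sample: str | None = None) -> VariantTable:
    """Read a variant table from TSV (canonical) or VCF.

    TSV needs columns site, ref_reads/total_reads and alt_reads or
    variant_reads.  VCF reading uses the per-sample allelic depths (AD);
    multiallelic records are split into one row per alternate allele with
    total reads = sum of that sample's allelic depths.  Malformed rows are
    skipped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "tsv":
        return _read_tsv(path, sample)
    if format == "vcf":
        return _read_vcf(path, sample)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path, sample: str | None) -> VariantTable:
    df = pd.read_csv(path, sep="\t")
    if "total_reads" not in df.columns:
        if {"ref_reads", "alt_reads"} <= set(df.columns):
            df["total_reads"] = df["ref_reads"] + df["alt_reads"]
        else:
            raise ValueError(f"{path}: no total_reads or ref_reads/alt_reads columns")
    if "variant_reads" not in df.columns:
        if "alt_reads" in df.columns:
            df["variant_reads"] = df["alt_reads"]
        else:
            raise ValueError(f"{path}: no variant_reads or alt_reads column")
    bad = (df["variant_reads"] > df["total_reads"]) | (df["total_reads"] < 0)
    if bad.any():
        logger.warning("%s: skipped %d malformed rows", path, int(bad.sum()))
        df = df[~bad]
    return VariantTable(df=df, sample=sample or path.stem)


def _read_vcf(path: Path, sample: str | None) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if not vcf.samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    if sample is None:
        sample = vcf.samples[0]
    try:
        si = vcf.samples.index(sample)
    except ValueError:
        raise ValueError(f"{path}: sample {sample!r} not in VCF") from None
    rows = []
    skipped = 0
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            skipped += 1
            continue
        depths = np.asarray(ad[si], dtype=np.int64)
        depths = depths[depths >= 0]  # missing entries are negative sentinels
        if depths.size < 2:
            skipped += 1
            continue
        total = int(depths.sum())
        for alt_idx, alt in enumerate(var.ALT, start=1):
            if alt_idx >= depths.size:
                skipped += 1
                continue
            rows.append(
                (f"{var.CHROM}:{var.POS}:{var.REF}>{alt}", total, int(depths[alt_idx]))
            )
    if skipped:
        logger.warning("%s: skipped %d records without usable depths", path, skipped)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return VariantTable(df=df, sample=sample)


def write_variants(table: VariantTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def freedman_diaconis_width(values: np.ndarray) -> int:
    """Freedman-Diaconis histogram bin width, rounded up to an integer >= 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 1
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    width = 2.0 * iqr / np.cbrt(v.size)
    return max(1, int(np.ceil(width)))


def histogram_equalize(
    a: VariantTable,
    b: VariantTable,
    bin_width: int | None = None,
    rng: np.random.Generator | int | None = 0,
) -> tuple[VariantTable, VariantTable]:
    """Equalize the total-read histograms of two paired samples.

    Per common-width bin, the sample with more variants is randomly pruned
    (uniformly, without replacement) down to the other sample's count, so
    the two output histograms agree exactly bin by bin.  Retained rows are
    passed through verbatim.  ``bin_width`` defaults to the
    Freedman-Diaconis width on the pooled total-read counts.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ta = a.df["total_reads"].to_numpy()
    tb = b.df["total_reads"].to_numpy()
    pooled = np.concatenate([ta, tb])
    if bin_width is None:
        bin_width = freedman_diaconis_width(pooled)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = int(pooled.min()) if pooled.size else 0
    hi = int(pooled.max()) if pooled.size else 0
    edges = np.arange(lo, hi + bin_width + 1, bin_width)

    bins_a = np.digitize(ta, edges, right=False)
    bins_b = np.digitize(tb, edges, right=False)

    keep_a = np.zeros(len(ta), dtype=bool)
    keep_b = np.zeros(len(tb), dtype=bool)
    for bin_id in np.union1d(bins_a, bins_b):
        idx_a = np.flatnonzero(bins_a == bin_id)
        idx_b = np.flatnonzero(bins_b == bin_id)
        target = min(len(idx_a), len(idx_b))
        for idx, keep in ((idx_a, keep_a), (idx_b, keep_b)):
            if len(idx) > target:
                chosen = rng.choice(idx, size=target, replace=False)
                keep[chosen] = True
            else:
                keep[idx] = True
    out_a = VariantTable(df=a.df[keep_a].reset_index(drop=True), sample=a.sample)
    out_b = VariantTable(df=b.df[keep_b].reset_index(drop=True), sample=b.sample)
    return out_a, out_b


def synthesize_paired_tables(
    freqs_primary: Sequence[float],
    freqs_met: Sequence[float],
    depth_mean: float = 100.0,
    depth_dispersion: float = 5.0,
    shared_fraction: float = 0.5,
    seed: int | np.random.Generator | None = 0,
) -> tuple[VariantTable, VariantTable]:
    """Synthetic paired tumor/metastasis variant tables.

    Emulates paired whole-exome read-count tables: per-site sequencing
    depth is drawn from a negative-binomial distribution with the given
    mean and dispersion (shape) parameter -- smaller dispersion means more
    depth variation -- and variant reads are Binomial(depth, freq).  A
    ``shared_fraction`` of the shorter site list appears in both samples
    under the same site id and the same underlying frequency; remaining
    sites are private.  Depths are drawn independently per sample, which is
    exactly the coverage bias the equalization procedure corrects.

    This generator is synthetic: it replaces controlled-access patient
    data and models only depth variation and binomial read sampling (no
    purity, contamination, or FFPE artifacts).
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    if depth_mean <= 0 or depth_dispersion <= 0:
        raise ValueError("depth parameters must be positive")
    fp = np.asarray(freqs_primary, dtype=float)
    fm = np.asarray(freqs_met, dtype=float)
    for f in (fp, fm):
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_shared = int(round(shared_fraction * min(fp.size, fm.size)))
    # shared sites take their frequency from the primary list
    shared_f = fp[:n_shared]

    def _one(freqs: np.ndarray, label: str, prefix: str, shared: np.ndarray) -> VariantTable:
        all_f = np.concatenate([shared, freqs[n_shared:] if label == "primary" else freqs[n_shared:]])
        ids = [f"shared_{i}" for i in range(len(shared))] + [
            f"{prefix}_{i}" for i in range(len(all_f) - len(shared))
        ]
        # negative binomial with mean m and shape r: p = r/(r+m)
        r = depth_dispersion
        p = r / (r + depth_mean)
        depth = rng.negative_binomial(r, p, size=len(all_f))
        depth = np.maximum(depth, 1)  # every synthesized site was covered
        alt = rng.binomial(depth, all_f)
        df = pd.DataFrame(
            {"site": ids, "total_reads": depth, "variant_reads": alt}
        )
        return VariantTable(df=df, sample=label)

    table_p = _one(fp, "primary", "p", shared_f)
    table_m = _one(fm, "metastasis", "m", shared_f)
    return table_p, table_m


def compare_tails(
    data_tail: CumulativeTail,
    model_tails: Sequence[CumulativeTail],
    labels: Sequence[str] | None = None,
    floor: float = 1e-12,
) -> pd.DataFrame:
    """Sup-distance and area between log10 tails of data vs. each model.

    Both curves are interpolated onto the intersection of their grids
    (step-function semantics would need the raw frequencies; linear
    interpolation of log10 T on the common range is used instead).  The
    sup metric ranks the models; the area metric breaks ties.  Tail values
    are floored at ``floor`` before taking logs.
    """
    if labels is None:
        labels = [f"model_{i}" for i in range(len(model_tails))]
    rows = []
    for label, mt in zip(labels, model_tails):
        lo = max(data_tail.grid.min(), mt.grid.min())
        hi = min(data_tail.grid.max(), mt.grid.max())
        if lo >= hi:
            raise ValueError(f"tail grids of data and {label} do not overlap")
        x = np.unique(
            np.concatenate(
                [
                    data_tail.grid[(data_tail.grid >= lo) & (data_tail.grid <= hi)],
                    mt.grid[(mt.grid >= lo) & (mt.grid <= hi)],
                ]
            )
        )
        ld = np.log10(np.maximum(np.interp(x, data_tail.grid, data_tail.T), floor))
        lm = np.log10(np.maximum(np.interp(x, mt.grid, mt.T), floor))
        diff = np.abs(ld - lm)
        sup = float(diff.max())
        area = float(np.trapezoid(diff, x)) if x.size > 1 else 0.0
        rows.append((label, sup, area))
    out = pd.DataFrame(rows, columns=["model", "sup_log10", "area_log10"])
    return out.sort_values(["sup_log10", "area_log10"]).reset_index(drop=True)
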