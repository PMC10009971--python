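"""Fragment-length summaries and the three per-sample classification features.

Only fragments with template length in [100, 250] bp enter any computation
(151 possible sizes). Fragments overlapping a retained variant are split
into ALT (mutation-bearing) and REF (reference-allele) records; tumor-derived
DNA is enriched for sub-mononucleosomal sizes, so ALT fragments of cancer
plasma are shifted left relative to the ~166 bp reference peak.

Features per sample (17 values total):

* f1 — count(ALT length <= 150) / count(ALT length > 150), clamped
  denominator;
* f2 — PHRED-scaled (-10*log10 p) one-tailed Fisher exact p for ALT
  over-representation in the 110-135 bp window versus REF, capped at 300;
* f3 — 15 windowed sums of lambda(s) = P(len=s | ALT) / P(len=s | REF),
  add-one smoothed, over non-overlapping 10-bp windows covering s=100..249.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .background import VariantPartition
from .io import F3_NAMES, FEATURE_COLUMNS, variant_key

log = logging.getLogger(__name__)

MIN_LEN = 100
MAX_LEN = 250
N_SIZES = MAX_LEN - MIN_LEN + 1  # 151
SIZES = np.arange(MIN_LEN, MAX_LEN + 1)
N_WINDOWS = 15
PHRED_CAP = 300.0


@dataclass
class FragmentFeatureVector:
    """Per-sample fragmentomic features: 1 + 1 + 15 = 17 values."""

    sample_id: str
    f1: float
    f2: float
    f3: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.f3 = np.asarray(self.f3, dtype=float)
        if self.f3.shape != (N_WINDOWS,):
            raise ValueError(f"f3 must have exactly {N_WINDOWS} entries")

    def to_row(self) -> list:
        return [self.sample_id, self.label, self.f1, self.f2, *self.f3.tolist()]


def filter_for_features(partition: VariantPartition, vaf_ceiling: float = 0.1) -> pd.DataFrame:
    """LB-unique variants with VAF strictly below the ceiling.

    High-VAF calls are dominated by germline/CH signal and are excluded from
    feature construction.
    """
    lb = partition.lb_unique
    return lb[lb["vaf"] < vaf_ceiling].reset_index(drop=True)


def restrict_lengths(fragments: pd.DataFrame) -> pd.DataFrame:
    """Keep fragment records with 100 <= length <= 250 (inclusive)."""
    m = (fragments["length"] >= MIN_LEN) & (fragments["length"] <= MAX_LEN)
    return fragments[m].reset_index(drop=True)


def _length_counts(lengths: np.ndarray) -> np.ndarray:
    lengths = np.asarray(lengths, dtype=int)
    if np.any((lengths < MIN_LEN) | (lengths > MAX_LEN)):
        raise ValueError("lengths outside [100,250]; apply restrict_lengths first")
    return np.bincount(lengths - MIN_LEN, minlength=N_SIZES).astype(float)


def flen_distribution(fragments: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Fragment-length frequency vector: percent of in-range fragments at each
    of the 151 sizes 100..250 bp. Entries sum to 100."""
    lengths = fragments["length"].to_numpy() if isinstance(fragments, pd.DataFrame) else fragments
    counts = _length_counts(lengths)
    total = counts.sum()
    if total == 0:
        raise ValueError("no fragments in the 100-250 bp range")
    return 100.0 * counts / total


def bin_short_long_ratios(
    genome_fragments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 5_000_000,
) -> pd.DataFrame:
    """Per-bin short/long fragment-count ratios over non-overlapping genomic
    bins (autosomes only; supply autosomal ``chrom_lengths``).

    Fragments on chromosomes absent from ``chrom_lengths`` (e.g. X/Y) are
    dropped. Short = 100-150 bp, long = 151-250 bp; a bin with zero long
    fragments gets ratio NaN (flagged missing, never infinity). Bin count per
    chromosome is ceil(L / bin_size).
    """
    frames = []
    for chrom, L in chrom_lengths.items():
        n_bins = math.ceil(L / bin_size)
        sub = genome_fragments[genome_fragments["chrom"] == chrom]
        if len(sub) and (sub["start"].max() >= L or sub["start"].min() < 0):
            raise ValueError(f"fragment start beyond chromosome {chrom} length {L}")
        lengths = sub["length"].to_numpy()
        in_range = (lengths >= MIN_LEN) & (lengths <= MAX_LEN)
        starts = sub["start"].to_numpy()[in_range]
        short = lengths[in_range] <= 150
        bins = starts // bin_size
        n_short = np.bincount(bins[short], minlength=n_bins)[:n_bins]
        n_long = np.bincount(bins[~short], minlength=n_bins)[:n_bins]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(n_long > 0, n_short / np.maximum(n_long, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin": np.arange(n_bins),
                    "n_short": n_short,
                    "n_long": n_long,
                    "ratio": ratio,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def feature1_short_long_fraction(alt_lengths: np.ndarray, boundary: int = 150) -> float:
    """Short-to-long ALT fragment ratio.

    Short: length <= boundary; long: length > boundary, so every in-range
    fragment is counted exactly once. The denominator is clamped at 1 when no
    long fragments exist (logged).
    """
    alt_lengths = np.asarray(alt_lengths, dtype=int)
    if alt_lengths.size == 0:
        raise ValueError("no ALT support: cannot compute short/long fraction")
    n_short = int(np.sum(alt_lengths <= boundary))
    n_long = int(np.sum(alt_lengths > boundary))
    if n_long == 0:
        log.warning("feature1: no long ALT fragments; denominator clamped to 1")
    return n_short / max(1, n_long)


def contingency_table(
    alt_lengths: np.ndarray, ref_lengths: np.ndarray, window: tuple[int, int] = (110, 135)
) -> tuple[int, int, int, int]:
    """(A, B, C, D): REF in/out of window, ALT in/out of window."""
    lo, hi = window
    alt_lengths = np.asarray(alt_lengths)
    ref_lengths = np.asarray(ref_lengths)
    a = int(np.sum((ref_lengths >= lo) & (ref_lengths <= hi)))
    b = int(ref_lengths.size - a)
    c = int(np.sum((alt_lengths >= lo) & (alt_lengths <= hi)))
    d = int(alt_lengths.size - c)
    return a, b, c, d


def feature2_size_enrichment(
    alt_lengths: np.ndarray,
    ref_lengths: np.ndarray,
    window: tuple[int, int] = (110, 135),
    alternative: str = "greater",
) -> float:
    """PHRED-scaled one-tailed Fisher exact p for ALT over-representation in
    the size-selection window, capped at 300."""
    a, b, c, d = contingency_table(alt_lengths, ref_lengths, window)
    if a + b == 0 or c + d == 0:
        raise ValueError("need at least one ALT and one REF fragment")
    # ALT row first: 'greater' tests ALT odds of falling inside the window
    p = stats.fisher_exact([[c, d], [a, b]], alternative=alternative).pvalue
    if p <= 0.0:
        return PHRED_CAP
    return min(PHRED_CAP, -10.0 * math.log10(p))


def feature3_lambda_profile(
    alt_lengths: np.ndarray,
    ref_lengths: np.ndarray,
    window_width: int = 10,
    smoothing: float = 1.0,
) -> np.ndarray:
    """Windowed sums of the ALT/REF size likelihood ratio lambda(s).

    Per-size counts get add-one (Laplace) smoothing before normalization so
    lambda stays finite and identical ALT/REF distributions give exactly
    lambda = 1 everywhere. 15 non-overlapping windows of ``window_width``
    sizes cover s = 100..249; s = 250 (incomplete trailing window) is
    dropped.
    """
    alt_lengths = np.asarray(alt_lengths)
    ref_lengths = np.asarray(ref_lengths)
    if alt_lengths.size == 0 or ref_lengths.size == 0:
        raise ValueError("need at least one ALT and one REF fragment")
    alt_c = _length_counts(alt_lengths) + smoothing
    ref_c = _length_counts(ref_lengths) + smoothing
    lam = (alt_c / alt_c.sum()) / (ref_c / ref_c.sum())
    usable = N_WINDOWS * window_width  # 150 of the 151 sizes
    return lam[:usable].reshape(N_WINDOWS, window_width).sum(axis=1)


def compute_sample_features(
    alt_lengths: np.ndarray,
    ref_lengths: np.ndarray,
    sample_id: str,
    label: str | None = None,
    boundary: int = 150,
    window: tuple[int, int] = (110, 135),
    window_width: int = 10,
) -> FragmentFeatureVector:
    """All three features for one sample's pooled in-range ALT/REF lengths."""
    return FragmentFeatureVector(
        sample_id=sample_id,
        f1=feature1_short_long_fraction(alt_lengths, boundary=boundary),
        f2=feature2_size_enrichment(alt_lengths, ref_lengths, window=window),
        f3=feature3_lambda_profile(alt_lengths, ref_lengths, window_width=window_width),
        label=label,
    )


def sample_alt_ref_lengths(
    retained_variants: pd.DataFrame, fragments: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Pool in-range ALT/REF lengths of fragments overlapping the retained
    variants of one sample (aggregation over all retained variants, not
    per-variant averaging)."""
    keys = set(variant_key(retained_variants))
    sub = fragments[fragments["variant_key"].isin(keys)]
    sub = restrict_lengths(sub)
    alt = sub.loc[sub["allele"] == "ALT", "length"].to_numpy()
    ref = sub.loc[sub["allele"] == "REF", "length"].to_numpy()
    return alt, ref


def build_feature_matrix(feature_vectors: list[FragmentFeatureVector]) -> pd.DataFrame:
    """Assemble the N x 17 feature matrix (plus sample_id and label columns),
    preserving input order."""
    rows = []
    for fv in feature_vectors:
        try:
            rows.append(fv.to_row())
        except Exception as e:  # pragma: no cover - defensive
            raise ValueError(f"sample {fv.sample_id!r}: {e}") from e
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def matrix_from_table(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, sample_ids) from a feature table; y is 1 for cancer."""
    X = features[["f1", "f2", *F3_NAMES]].to_numpy(dtype=float)
    y = (features["label"] == "cancer").to_numpy(dtype=int)
    return X, y, features["sample_id"].to_numpy()
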