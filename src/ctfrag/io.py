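"""Tab-separated table formats, run configuration, and metrics serialization.

All tables are UTF-8 TSV with a required header; lines starting with ``#``
are comments. Variant positions are 1-based (VCF convention); fragment
lengths are untransformed template lengths in bp.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

VARIANT_COLUMNS = ["sample_id", "compartment", "chrom", "pos", "ref", "alt", "ad", "dp", "vaf"]
FRAGMENT_COLUMNS = ["sample_id", "variant_key", "length", "allele"]
GENOME_FRAGMENT_COLUMNS = ["sample_id", "chrom", "start", "length"]
COMPARTMENTS = ("plasma", "wbc", "tumor")
ALLELES = ("ALT", "REF")

F3_NAMES = [f"f3_{k:02d}" for k in range(1, 16)]
FEATURE_COLUMNS = ["sample_id", "label", "f1", "f2", *F3_NAMES]


class TableFormatError(ValueError):
    """A table violates the dialect or a row-level invariant."""


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    return df


def _coerce(df: pd.DataFrame, col: str, kind: str, path: Path) -> pd.Series:
    try:
        return df[col].astype(int if kind == "int" else float)
    except ValueError:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise TableFormatError(
            f"{path}: row {bad + 2}: non-numeric value {df[col][bad]!r} in column {col!r}"
        ) from None


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant TSV into a validated DataFrame (one row per call).

    Raises :class:`TableFormatError` with a row number on the first violated
    invariant (``ad <= dp``, ``vaf == ad/dp`` within 1e-6, known compartment,
    duplicate variant key within a sample/compartment).
    """
    path = Path(path)
    df = _read_tsv(path, VARIANT_COLUMNS)
    for col, kind in [("pos", "int"), ("ad", "int"), ("dp", "int"), ("vaf", "float")]:
        df[col] = _coerce(df, col, kind, path)
    bad = df.index[~df["compartment"].isin(COMPARTMENTS)]
    if len(bad):
        raise TableFormatError(
            f"{path}: row {bad[0] + 2}: unknown compartment {df['compartment'][bad[0]]!r}"
        )
    bad = df.index[(df["ad"] < 0) | (df["dp"] < 1) | (df["ad"] > df["dp"])]
    if len(bad):
        i = bad[0]
        raise TableFormatError(
            f"{path}: row {i + 2}: depth invariant violated "
            f"(ad={df['ad'][i]}, dp={df['dp'][i]}; requires 0 <= ad <= dp, dp >= 1)"
        )
    bad = df.index[(df["vaf"] - df["ad"] / df["dp"]).abs() > 1e-6]
    if len(bad):
        i = bad[0]
        raise TableFormatError(
            f"{path}: row {i + 2}: vaf={df['vaf'][i]} inconsistent with ad/dp="
            f"{df['ad'][i] / df['dp'][i]:.8f}"
        )
    key = df["sample_id"] + "/" + df["compartment"] + "/" + variant_key(df)
    dup = df.index[key.duplicated()]
    if len(dup):
        raise TableFormatError(
            f"{path}: row {dup[0] + 2}: duplicate variant key within sample/compartment"
        )
    return df.reset_index(drop=True)


def variant_key(df: pd.DataFrame) -> pd.Series:
    """``chrom:pos:ref:alt`` identifier series for a variant table."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=VARIANT_COLUMNS)


def read_fragment_table(path: str | Path) -> pd.DataFrame:
    """Read fragment records. No length filtering happens at read time;
    ``fragmentomics.restrict_lengths`` is the explicit downstream step."""
    path = Path(path)
    df = _read_tsv(path, FRAGMENT_COLUMNS)
    df["length"] = _coerce(df, "length", "int", path)
    bad = df.index[df["length"] < 1]
    if len(bad):
        raise TableFormatError(f"{path}: row {bad[0] + 2}: fragment length must be >= 1")
    # allele labels accepted case-insensitively
    df["allele"] = df["allele"].str.upper()
    bad = df.index[~df["allele"].isin(ALLELES)]
    if len(bad):
        raise TableFormatError(
            f"{path}: row {bad[0] + 2}: unknown allele label {df['allele'][bad[0]]!r}"
        )
    return df.reset_index(drop=True)


def write_fragment_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=FRAGMENT_COLUMNS)


def read_genome_fragment_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_tsv(path, GENOME_FRAGMENT_COLUMNS)
    for col in ("start", "length"):
        df[col] = _coerce(df, col, "int", path)
    return df.reset_index(drop=True)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_tsv(path, FEATURE_COLUMNS)
    for col in FEATURE_COLUMNS[2:]:
        df[col] = _coerce(df, col, "float", path)
    return df.reset_index(drop=True)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Thresholds mirror the assay definition: plasma variants are screened
    against the WBC background at ``alpha`` and capped at ``vaf_ceiling``;
    fragment features use the short/long ``boundary`` and the size-selection
    ``enrichment_window``.
    """

    variants_path: str | None = None
    fragments_path: str | None = None
    out_dir: str = "ctfrag_out"
    rng_seed: int = 0
    alpha: float = 0.05
    vaf_ceiling: float = 0.1
    boundary: int = 150
    enrichment_window: tuple[int, int] = (110, 135)
    window_width: int = 10
    log_level: str = "INFO"
    simulation: dict[str, Any] = field(default_factory=dict)
    classifier_grid: dict[str, list] | None = None
    n_permutations: int = 0
    single_feature_aucs: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if not 0.0 < self.vaf_ceiling <= 1.0:
            raise ValueError(f"vaf_ceiling must be in (0,1], got {self.vaf_ceiling}")
        if not 100 <= self.boundary <= 250:
            raise ValueError(f"boundary must lie in [100,250], got {self.boundary}")
        lo, hi = self.enrichment_window
        if not (100 <= lo <= hi <= 250):
            raise ValueError(f"enrichment window must be within [100,250], got {lo},{hi}")
        self.enrichment_window = (int(lo), int(hi))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["enrichment_window"] = list(d["enrichment_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "enrichment_window" in d:
            d["enrichment_window"] = tuple(d["enrichment_window"])
        return cls(**d)


# ---------------------------------------------------------------------------
# metrics serialization: floats rendered to 6 significant digits for stable diffs


def _round_sig(x: Any, sig: int = 6) -> Any:
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        if not math.isfinite(x) or x == 0.0:
            return x
        return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def write_metrics(metrics: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_round_sig(metrics), indent=2, sort_keys=True) + "\n")


def read_metrics(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
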