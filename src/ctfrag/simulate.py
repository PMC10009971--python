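"""Synthetic discovery/validation cohorts for the full analysis chain.

The generator emulates the statistical structure of a deep targeted-panel
liquid-biopsy study of early-stage hepatocellular carcinoma versus healthy
controls:

* a pooled WBC cohort whose VAFs follow a zero-inflated beta (point mass of
  absent calls plus a skewed positive clonal-hematopoiesis/germline
  component);
* plasma variant sets of which ~41% are WBC-shared, with plasma VAFs coupled
  to the matched WBC VAFs tightly enough that the pooled Pearson correlation
  is ~0.95 on recorded (AD/DP) frequencies;
* the remaining plasma variants are benign somatic calls (both classes) or
  tumor-derived calls (cancer only, VAF below the feature ceiling);
* fragment records per variant: REF fragments always follow the ~166 bp
  mononucleosomal reference law; ALT fragments of tumor-derived variants mix
  in a left-shifted ~150 bp tumor component; every other ALT fragment
  follows the reference law. All lengths are discretized on [100, 250] bp.

Truth labels (per-sample class, per-variant source) are carried alongside so
downstream filtering and classification can be scored against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .io import variant_key

TRUTH_SOURCES = ("wbc_shared", "tumor_derived", "benign_unique")


@dataclass
class SimulationConfig:
    """Study-design and distributional parameters of the synthetic cohorts.

    Cohort sizes follow the study design (55+55 discovery, 54+53
    validation, 110 pooled WBC samples); per-sample mutation load uses the
    reported median of 73 plasma calls with a ~41% WBC-shared fraction.
    Sequencing depth is lognormal with median 500x (UMI-consensus coverage
    scale). ``shared_logit_sd`` is the coupling-noise constant tuned once so
    that recorded shared VAFs reach the ~0.95 target correlation.
    """

    n_cancer_discovery: int = 55
    n_healthy_discovery: int = 55
    n_cancer_validation: int = 54
    n_healthy_validation: int = 53
    n_wbc_samples: int = 110
    wbc_sites_per_sample: int = 180
    mutations_per_sample: float = 73.0
    wbc_shared_fraction: float = 0.41
    background_pi0: float = 0.6
    background_a: float = 0.3
    background_b: float = 20.0
    wbc_vaf_correlation: float = 0.95
    shared_logit_sd: float = 0.15
    depth_median: float = 500.0
    depth_log_sd: float = 0.3
    tumor_fraction: float = 0.35
    unique_vaf_a: float = 5.0
    unique_vaf_b: float = 45.0
    tumor_vaf_ceiling: float = 0.1
    ref_length_mode: int = 166
    ref_length_sd: float = 9.0
    tumor_length_mode: int = 150
    tumor_length_sd: float = 8.0
    tumor_mixture_weight: float = 0.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wbc_shared_fraction", "background_pi0", "tumor_fraction",
                     "tumor_mixture_weight", "tumor_vaf_ceiling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("ref_length_mode", "tumor_length_mode"):
            v = getattr(self, name)
            if not 100 <= v <= 250:
                raise ValueError(f"{name} must lie in [100,250] bp, got {v}")
        for name in ("n_cancer_discovery", "n_healthy_discovery", "n_cancer_validation",
                     "n_healthy_validation", "n_wbc_samples", "wbc_sites_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mutations_per_sample <= 0 or self.depth_median <= 0:
            raise ValueError("mutations_per_sample and depth_median must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class CohortData:
    """Full synthetic dataset: variant/fragment tables plus truth labels."""

    wbc_variants: pd.DataFrame
    plasma_variants: pd.DataFrame
    fragments: pd.DataFrame
    samples: pd.DataFrame          # sample_id, cohort (discovery/validation), label
    truth_labels: pd.DataFrame     # sample_id, variant_key, source
    config: SimulationConfig = field(repr=False, default=None)


def discrete_length_pmf(mode: float, sd: float) -> np.ndarray:
    """Discretized truncated-normal pmf over the 151 sizes 100..250 bp,
    proportional to the normal density at each integer size."""
    s = np.arange(100, 251, dtype=float)
    w = np.exp(-0.5 * ((s - mode) / sd) ** 2)
    return w / w.sum()


def _draw_lengths(pmf: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(np.arange(100, 251), size=n, p=pmf)


def _draw_depths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    dp = rng.lognormal(np.log(config.depth_median), config.depth_log_sd, n)
    return np.maximum(50, dp).astype(int)


def simulate_wbc_cohort(config: SimulationConfig, rng: np.random.Generator,
                        sample_ids: list[str] | None = None) -> pd.DataFrame:
    """WBC variant tables for the pooled background cohort.

    Each sample assays ``wbc_sites_per_sample`` panel sites; a site's latent
    VAF is 0 with probability pi0, otherwise Beta(a, b). Recorded
    AD = Binomial(DP, latent VAF) with DP lognormal (median ~500x). The
    returned frame keeps the internal ``latent_vaf`` column for shared-variant
    coupling; table writers drop it.
    """
    if sample_ids is None:
        sample_ids = [f"wbc_{i + 1:03d}" for i in range(config.n_wbc_samples)]
    n_sites = config.wbc_sites_per_sample
    n_total = len(sample_ids) * n_sites
    is_zero = rng.random(n_total) < config.background_pi0
    latent = np.where(
        is_zero, 0.0, rng.beta(config.background_a, config.background_b, n_total)
    )
    dp = _draw_depths(config, n_total, rng)
    ad = rng.binomial(dp, latent)
    site = np.tile(np.arange(n_sites), len(sample_ids))
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_sites),
            "compartment": "wbc",
            "chrom": np.char.add("chr", ((site % 13) + 1).astype(str)),
            "pos": 10_000 + site * 100,
            "ref": "A",
            "alt": "T",
            "ad": ad,
            "dp": dp,
            "vaf": ad / dp,
            "latent_vaf": latent,
        }
    )
    return df


def _unique_vafs(config: SimulationConfig, n: int, rng: np.random.Generator,
                 ceiling: float | None) -> np.ndarray:
    v = rng.beta(config.unique_vaf_a, config.unique_vaf_b, n)
    if ceiling is not None:
        for _ in range(100):
            over = v >= ceiling
            if not over.any():
                break
            v[over] = rng.beta(config.unique_vaf_a, config.unique_vaf_b, int(over.sum()))
        v = np.minimum(v, ceiling * (1 - 1e-9))
    return v


def simulate_plasma_sample(
    config: SimulationConfig,
    class_label: str,
    rng: np.random.Generator,
    sample_id: str,
    wbc_reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One plasma sample: (variants, fragments, truth labels).

    Shared variants copy the matched WBC latent VAF with lognormal-logit
    noise; tumor-derived variants (cancer only) draw ALT fragment lengths
    from the tumor mixture; every other fragment follows the reference law.
    """
    if class_label not in ("cancer", "healthy"):
        raise ValueError(f"class_label must be cancer or healthy, got {class_label!r}")
    n_mut = max(5, rng.poisson(config.mutations_per_sample))
    n_shared = rng.binomial(n_mut, config.wbc_shared_fraction)
    n_rest = n_mut - n_shared
    if class_label == "cancer":
        n_tumor = rng.binomial(n_rest, config.tumor_fraction)
    else:
        n_tumor = 0
    n_benign = n_rest - n_tumor

    # --- shared variants: couple to matched WBC latent VAFs
    if wbc_reference is not None:
        pos = wbc_reference[wbc_reference["latent_vaf"] > 0]
        # cap at the available positive sites to keep per-sample keys unique
        take = pos.sample(n=min(n_shared, len(pos)), random_state=int(rng.integers(2**31)))
        wbc_latent = take["latent_vaf"].to_numpy()
        shared_keys = variant_key(take).to_numpy()
    else:
        wbc_latent = rng.beta(config.background_a, config.background_b, n_shared)
        shared_keys = np.array([f"chr{(i % 13) + 1}:{10_000 + i * 100}:A:T"
                                for i in range(n_shared)])
    n_shared = wbc_latent.size
    noise = rng.normal(0.0, config.shared_logit_sd, n_shared)
    shared_latent = expit(logit(np.clip(wbc_latent, 1e-9, 1 - 1e-9)) + noise)

    # --- unique variants (benign both classes, tumor-derived cancer only)
    tumor_latent = _unique_vafs(config, n_tumor, rng, config.tumor_vaf_ceiling)
    benign_latent = _unique_vafs(config, n_benign, rng, None)
    latent = np.concatenate([shared_latent, tumor_latent, benign_latent])
    source = np.array(
        ["wbc_shared"] * n_shared + ["tumor_derived"] * n_tumor + ["benign_unique"] * n_benign
    )
    n_var = latent.size
    uniq_idx = np.arange(n_tumor + n_benign)
    unique_keys = np.array(
        [f"chr{(i % 13) + 1}:{5_000_000 + i * 100}:C:G" for i in uniq_idx]
    )
    keys = np.concatenate([shared_keys, unique_keys])

    dp = _draw_depths(config, n_var, rng)
    ad = np.maximum(1, rng.binomial(dp, latent))  # a called variant has >= 1 ALT read
    chrom, pos_, ref, alt = _split_keys(keys)
    variants = pd.DataFrame(
        {
            "sample_id": sample_id,
            "compartment": "plasma",
            "chrom": chrom,
            "pos": pos_,
            "ref": ref,
            "alt": alt,
            "ad": ad,
            "dp": dp,
            "vaf": ad / dp,
        }
    )
    truth = pd.DataFrame({"sample_id": sample_id, "variant_key": keys, "source": source})

    # --- fragment records
    ref_pmf = discrete_length_pmf(config.ref_length_mode, config.ref_length_sd)
    tum_pmf = discrete_length_pmf(config.tumor_length_mode, config.tumor_length_sd)
    n_alt_frags = np.maximum(1, rng.poisson(ad))
    n_ref_frags = rng.poisson(dp - ad)
    frag_keys, frag_len, frag_allele = [], [], []
    for i in range(n_var):
        na, nr = int(n_alt_frags[i]), int(n_ref_frags[i])
        if source[i] == "tumor_derived":
            alt_len = draw_tumor_alt_lengths(config, na, rng, ref_pmf, tum_pmf)
        else:
            alt_len = _draw_lengths(ref_pmf, na, rng)
        ref_len = _draw_lengths(ref_pmf, nr, rng)
        frag_keys.append(np.repeat(keys[i], na + nr))
        frag_len.append(np.concatenate([alt_len, ref_len]))
        frag_allele.append(np.array(["ALT"] * na + ["REF"] * nr))
    fragments = pd.DataFrame(
        {
            "sample_id": sample_id,
            "variant_key": np.concatenate(frag_keys),
            "length": np.concatenate(frag_len).astype(np.int16),
            "allele": np.concatenate(frag_allele),
        }
    )
    return variants, fragments, truth


def draw_tumor_alt_lengths(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator,
    ref_pmf: np.ndarray | None = None,
    tum_pmf: np.ndarray | None = None,
) -> np.ndarray:
    """ALT lengths of a tumor-derived variant: mixture of the ~150 bp tumor
    component (weight ``tumor_mixture_weight``) and the reference law."""
    if ref_pmf is None:
        ref_pmf = discrete_length_pmf(config.ref_length_mode, config.ref_length_sd)
    if tum_pmf is None:
        tum_pmf = discrete_length_pmf(config.tumor_length_mode, config.tumor_length_sd)
    from_tumor = rng.random(n) < config.tumor_mixture_weight
    out = np.empty(n, dtype=int)
    out[from_tumor] = _draw_lengths(tum_pmf, int(from_tumor.sum()), rng)
    out[~from_tumor] = _draw_lengths(ref_pmf, int((~from_tumor).sum()), rng)
    return out


def _split_keys(keys: np.ndarray) -> tuple[list, list, list, list]:
    parts = [k.split(":") for k in keys]
    return (
        [p[0] for p in parts],
        [int(p[1]) for p in parts],
        [p[2] for p in parts],
        [p[3] for p in parts],
    )


def _simulate_arm(
    config: SimulationConfig,
    rng: np.random.Generator,
    cohort: str,
    n_cancer: int,
    n_healthy: int,
    wbc_by_sample: dict[str, pd.DataFrame] | None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    v_frames, f_frames, t_frames, rows = [], [], [], []
    labels = ["cancer"] * n_cancer + ["healthy"] * n_healthy
    for j, label in enumerate(labels):
        sid = f"{cohort[:4]}_{label}_{(j if label == 'cancer' else j - n_cancer) + 1:03d}"
        ref = wbc_by_sample.get(sid) if wbc_by_sample else None
        v, f, t = simulate_plasma_sample(config, label, rng, sid, wbc_reference=ref)
        v_frames.append(v)
        f_frames.append(f)
        t_frames.append(t)
        rows.append({"sample_id": sid, "cohort": cohort, "label": label})
    if not rows:  # empty arm (e.g. no validation cohort requested)
        empty_v = pd.DataFrame(
            columns=["sample_id", "compartment", "chrom", "pos", "ref", "alt", "ad", "dp", "vaf"]
        )
        empty_f = pd.DataFrame(columns=["sample_id", "variant_key", "length", "allele"])
        empty_t = pd.DataFrame(columns=["sample_id", "variant_key", "source"])
        return empty_v, empty_f, empty_t, pd.DataFrame(columns=["sample_id", "cohort", "label"])
    return (
        pd.concat(v_frames, ignore_index=True),
        pd.concat(f_frames, ignore_index=True),
        pd.concat(t_frames, ignore_index=True),
        pd.DataFrame(rows),
    )


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Full synthetic study: WBC background cohort plus discovery and
    validation plasma cohorts with truth labels.

    Discovery plasma samples are paired 1:1 with the WBC cohort samples
    (matched buffy coat); validation samples are unpaired. The validation
    cohort consumes an independent child seed stream of the master seed.
    """
    master = np.random.SeedSequence(config.rng_seed)
    ss_wbc, ss_disc, ss_val = master.spawn(3)
    rng_wbc = np.random.default_rng(ss_wbc)

    n_disc = config.n_cancer_discovery + config.n_healthy_discovery
    disc_ids = [f"disc_cancer_{i + 1:03d}" for i in range(config.n_cancer_discovery)] + [
        f"disc_healthy_{i + 1:03d}" for i in range(config.n_healthy_discovery)
    ]
    # WBC samples pair with discovery plasma; any extras are unpaired controls
    wbc_ids = disc_ids[: config.n_wbc_samples] + [
        f"wbc_extra_{i + 1:03d}" for i in range(max(0, config.n_wbc_samples - n_disc))
    ]
    wbc = simulate_wbc_cohort(config, rng_wbc, sample_ids=wbc_ids)
    wbc_by_sample = {sid: g for sid, g in wbc.groupby("sample_id")}

    dv, df_, dt, ds = _simulate_arm(
        config, np.random.default_rng(ss_disc), "discovery",
        config.n_cancer_discovery, config.n_healthy_discovery, wbc_by_sample,
    )
    vv, vf, vt, vs = _simulate_arm(
        config, np.random.default_rng(ss_val), "validation",
        config.n_cancer_validation, config.n_healthy_validation, None,
    )
    def _cat(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
        frames = [f for f in (a, b) if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else a

    return CohortData(
        wbc_variants=wbc,
        plasma_variants=_cat(dv, vv),
        fragments=_cat(df_, vf),
        samples=_cat(ds, vs),
        truth_labels=_cat(dt, vt),
        config=config,
    )
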