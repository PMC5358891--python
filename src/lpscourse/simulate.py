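"""Synthetic data with planted ground truth.

Emulates the statistical structure of a dense LPS stimulation time course in
monocyte-derived macrophages measured by CAGE: 3 donors, 26 timepoints from
0 min to 48 h, promoter-level TPM with overdispersed count noise, injected
outlier spikes, monocyte/macrophage condition-group profiles, planted motif
activities, enhancer-promoter pairs in which the enhancer peaks first, and a
GWAS summary-statistic panel with an excess of significant variants near a
chosen TSS subset.

Noise model
-----------
Expression of feature ``f`` at time ``t`` in donor ``d`` is

    TPM[f,t,d] ~ NB( mu_f(t) * D[f,d] * eps[f,t,d] * L/1e6, alpha ) * 1e6/L

where ``mu_f`` is a deterministic archetype kernel, ``D`` a per-(feature,
donor) lognormal biological replicate effect, ``eps`` a per-cell lognormal
technical factor, and the negative binomial (Gamma-Poisson, dispersion
``alpha``) models CAGE tag counting at library size ``L``. Donor-level
offsets are what make pooled-across-donor outlier detection behave the way
it does on real replicate data; without them every flat stretch of a profile
would look like i.i.d. noise to the smoother.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable, TimeCourseTensor
from .errors import ConfigError, CoordinateError

#: the 26-point sampling grid, in minutes: every 15 min to 1 h, roughly every
#: 20-30 min to 4 h, hourly to 8 h, 2-hourly to 24 h, then 36 h and 48 h.
DEFAULT_TIME_GRID = (
    0, 15, 30, 45, 60, 80, 100, 120, 150, 180, 210, 240,
    300, 360, 420, 480, 600, 720, 840, 960, 1080, 1200,
    1320, 1440, 2160, 2880,
)

ARCHETYPES = (
    "immediate_early",
    "early_transient",
    "intermediate_wave",
    "late_sustained",
    "repressed",
    "flat",
)

DEFAULT_ARCHETYPE_MIX = {
    "immediate_early": 0.15,
    "early_transient": 0.20,
    "intermediate_wave": 0.20,
    "late_sustained": 0.15,
    "repressed": 0.15,
    "flat": 0.15,
}


@dataclass(frozen=True)
class SimConfig:
    """All tunables of the synthetic study, with the defaults that define it.

    Rates and proportions live in [0, 1]; fold parameters are >= 1. The GWAS
    block is scaled down from genome-wide arrays: 10k variants on a 50 Mb
    genome with a permissive significance threshold of 0.02 keeps both the
    expected number of "significant" variants and the variant count per
    placement window proportional to the real regime.
    """

    n_features: int = 2000
    n_enhancers: int = 200
    n_donors: int = 3
    time_grid_minutes: tuple = DEFAULT_TIME_GRID
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX)
    )
    donor_noise_cv: float = 0.05     # per-cell lognormal technical noise
    donor_effect_cv: float = 0.4     # per-(feature,donor) replicate offset
    count_dispersion: float = 0.005  # NB dispersion alpha; 0 -> Poisson
    library_size: int = 20_000_000   # CAGE tags per sample; 0 -> no counting
    spike_rate: float = 0.01         # fraction of features given one spike
    spike_magnitude: float = 10.0    # fold applied to the spiked cell
    seed: int = 0
    # condition-group block
    frac_candidates: float = 0.1     # fraction planted to meet all criteria
    condition_noise_cv: float = 0.2
    # motif block
    n_motifs: int = 10
    mara_noise_sd: float = 0.1
    # enhancer block
    enhancer_lead_minutes: int = 120
    # GWAS block
    genome_length: int = 50_000_000
    n_variants: int = 10_000
    frac_enriched_tss: float = 0.1
    enrichment_fold: float = 10.0
    sig_p_threshold: float = 0.02
    placement_window: int = 30_000   # half-width of the enrichment window

    def __post_init__(self) -> None:
        for name in ("n_features", "n_donors", "n_motifs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_enhancers", "n_variants", "library_size"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        grid = tuple(self.time_grid_minutes)
        if len(grid) < 2 or grid[0] != 0 or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ConfigError(
                "time_grid_minutes must be strictly increasing and start at 0"
            )
        mix = dict(self.archetype_mix)
        unknown = set(mix) - set(ARCHETYPES)
        if unknown:
            raise ConfigError(f"archetype_mix has unknown archetypes: {unknown}")
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
            raise ConfigError("archetype_mix proportions must be >= 0 and sum to 1")
        for name in (
            "spike_rate", "frac_candidates", "frac_enriched_tss", "sig_p_threshold",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("spike_magnitude", "enrichment_fold"):
            if getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "donor_noise_cv", "donor_effect_cv", "count_dispersion",
            "condition_noise_cv", "mara_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["time_grid_minutes"] = list(self.time_grid_minutes)
        out["archetype_mix"] = dict(self.archetype_mix)
        return out


@dataclass
class SimTruth:
    """Planted ground truth, the oracle for every downstream recovery test."""

    cluster_label: pd.Series | None = None          # feature -> archetype
    outlier_mask: np.ndarray | None = None          # (F, T, D) bool
    class_label: pd.Series | None = None            # condition-matrix classes
    candidate_ids: set | None = None                # features meeting all criteria
    planted_activity: pd.DataFrame | None = None    # motif x sample
    pairs: pd.DataFrame | None = None               # enhancer_id, promoter_id, lead
    enriched_tss_ids: set | None = None
    variant_sig_flag: pd.Series | None = None       # variant_id -> bool


# ---------------------------------------------------------------------------
# archetype kernels

def _gamma_kernel(t: np.ndarray, peak: float, shape: float = 3.0) -> np.ndarray:
    """Transient response: 0 at t=0, maximum exactly at t=peak, decay after."""
    x = np.maximum(t, 0.0) / peak
    return x ** shape * np.exp(shape * (1.0 - x))


def archetype_kernel(name: str, t: np.ndarray) -> np.ndarray:
    """Unit-height temporal kernel for one response archetype."""
    t = np.asarray(t, dtype=float)
    if name == "immediate_early":
        return _gamma_kernel(t, 45.0, shape=4.0)
    if name == "early_transient":
        return _gamma_kernel(t, 150.0, shape=3.0)
    if name == "intermediate_wave":
        return _gamma_kernel(t, 420.0, shape=3.0)
    if name == "late_sustained":
        k = 1.0 / (1.0 + np.exp(-(t - 600.0) / 180.0))
        return (k - k[0]) / (1.0 - k[0])
    if name == "repressed":
        return np.exp(-t / 400.0)
    if name == "flat":
        return np.full_like(t, 0.5)
    raise ConfigError(f"unknown archetype {name!r}")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplicative noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with Var = m + alpha m^2."""
    mean = np.maximum(mean, 0.0)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def _observe(
    rng: np.random.Generator, expected_tpm: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Turn expected TPM into observed TPM via tag counting at library size."""
    if config.library_size <= 0:
        return expected_tpm.copy()
    scale = config.library_size / 1e6
    counts = _nb_counts(rng, expected_tpm * scale, config.count_dispersion)
    return counts / scale


# ---------------------------------------------------------------------------
# time course

def gen_timecourse(
    config: SimConfig,
) -> tuple[TimeCourseTensor, pd.DataFrame, SimTruth]:
    """Simulate the 3-donor LPS time course with known archetypes and spikes.

    Returns the TPM tensor, the sample design table, and a SimTruth carrying
    the per-feature archetype label and the injected-spike mask.
    """
    rng = np.random.default_rng([config.seed, 1])
    t = np.asarray(config.time_grid_minutes, dtype=float)
    n_f, n_t, n_d = config.n_features, len(t), config.n_donors
    if n_d < 1:
        raise ConfigError("n_donors must be >= 1")

    names = list(config.archetype_mix)
    probs = np.array([config.archetype_mix[n] for n in names])
    labels = rng.choice(names, size=n_f, p=probs)

    scale = rng.lognormal(mean=math.log(30.0), sigma=0.8, size=n_f)
    baseline = 0.15 * scale + 2.0

    kernels = {name: archetype_kernel(name, t) for name in names}
    mean_profile = np.empty((n_f, n_t))
    for i, (lab, s, b) in enumerate(zip(labels, scale, baseline)):
        mean_profile[i] = b + s * kernels[lab]

    donor_effect = _lognormal_factor(rng, config.donor_effect_cv, (n_f, 1, n_d))
    cell_noise = _lognormal_factor(rng, config.donor_noise_cv, (n_f, n_t, n_d))
    expected = mean_profile[:, :, None] * donor_effect * cell_noise
    values = _observe(rng, expected, config).astype(float)

    # spike injection: one randomly chosen cell per selected feature
    mask = np.zeros((n_f, n_t, n_d), dtype=bool)
    if config.spike_rate > 0:
        spiked = np.flatnonzero(rng.random(n_f) < config.spike_rate)
        for i in spiked:
            ti = rng.integers(n_t)
            di = rng.integers(n_d)
            values[i, ti, di] *= config.spike_magnitude
            mask[i, ti, di] = True

    feature_ids = [f"p{i:05d}" for i in range(n_f)]
    donors = [f"donor{d + 1}" for d in range(n_d)]
    tensor = TimeCourseTensor(feature_ids, t, donors, values)

    design = pd.DataFrame(
        [
            {
                "sample_id": f"{donor}_t{int(tp)}",
                "donor": donor,
                "timepoint_minutes": int(tp),
                "condition_group": "LPS_MDM_t",
            }
            for donor in donors
            for tp in t
        ]
    )
    truth = SimTruth(
        cluster_label=pd.Series(labels, index=feature_ids, name="archetype"),
        outlier_mask=mask,
    )
    return tensor, design, truth


# ---------------------------------------------------------------------------
# condition-group matrix

_CONDITION_GROUPS = (
    "unstimulated_monocyte",
    "unstimulated_MDM",
    "IFN_monocyte",
    "inflammatory_monocyte",
)

#: group-mean multipliers (relative to a feature's unit scale) per class.
#: "candidate" meets every criterion with >= 1.6x margin on each threshold;
#: every other class breaks at least one criterion with >= 2x margin.
_CLASS_MEANS = {
    # mono, MDM, IFN_mono, inflammatory_mono
    "candidate": (40.0, 4.0, 10.0, 160.0),
    "flat": (10.0, 10.0, 10.0, 10.0),
    "down_not_specific": (40.0, 4.0, 10.0, 20.0),
    "specific_not_down": (40.0, 40.0, 10.0, 160.0),
    "mdm_up": (8.0, 40.0, 8.0, 8.0),
}


def gen_condition_matrix(
    config: SimConfig,
) -> tuple[ExpressionTable, pd.DataFrame, SimTruth]:
    """Monocyte / MDM / stimulated-monocyte group profiles with a planted
    subset that is >= 5-fold down in MDM and specifically induced by the
    inflammatory stimulus; all other features violate >= 1 criterion."""
    rng = np.random.default_rng([config.seed, 2])
    n_f = config.n_features
    classes = list(_CLASS_MEANS)
    others = [c for c in classes if c != "candidate"]
    n_cand = int(round(config.frac_candidates * n_f))
    labels = np.array(
        ["candidate"] * n_cand
        + [others[i % len(others)] for i in range(n_f - n_cand)]
    )
    rng.shuffle(labels)

    unit = rng.lognormal(mean=0.0, sigma=0.5, size=n_f)
    n_rep = 3
    sample_rows, columns = [], []
    for group in _CONDITION_GROUPS:
        for r in range(n_rep):
            sid = f"{group}_r{r + 1}"
            columns.append(sid)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "donor": f"donor{r + 1}",
                    "timepoint_minutes": None,
                    "condition_group": group,
                }
            )
    design = pd.DataFrame(sample_rows)

    group_means = np.array([_CLASS_MEANS[lab] for lab in labels]) * unit[:, None]
    values = np.repeat(group_means, n_rep, axis=1)
    values = values * _lognormal_factor(
        rng, config.condition_noise_cv, values.shape
    )

    feature_ids = [f"c{i:05d}" for i in range(n_f)]
    table = ExpressionTable(
        pd.DataFrame(values, index=feature_ids, columns=columns), unit="tpm"
    )
    label_series = pd.Series(labels, index=feature_ids, name="class")
    truth = SimTruth(
        class_label=label_series,
        candidate_ids=set(label_series.index[label_series == "candidate"]),
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# GWAS panel

def gen_genome_and_variants(
    config: SimConfig, tss: pd.DataFrame
) -> tuple[pd.DataFrame, SimTruth]:
    """Uniform variant panel with planted excess significance near a subset
    of TSS.

    ``tss`` needs columns feature_id, chrom, tss_pos (0-based). Null p-values
    are uniform(0,1); within ``placement_window`` of an enriched TSS the
    probability that p < sig_p_threshold is multiplied by enrichment_fold.
    """
    rng = np.random.default_rng([config.seed, 3])
    if (tss["tss_pos"] < 0).any() or (tss["tss_pos"] >= config.genome_length).any():
        raise CoordinateError("tss positions outside genome bounds")

    n_v = config.n_variants
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i:06d}" for i in range(n_v)],
            "chrom": "chr1",
            "pos": np.sort(rng.integers(1, config.genome_length + 1, size=n_v))
            if n_v
            else np.array([], dtype=int),
            "pvalue": rng.uniform(0.0, 1.0, size=n_v),
        }
    )
    # uniform(0,1) can in principle return exactly 0, which the p-value
    # schema forbids; nudge into (0, 1].
    variants["pvalue"] = variants["pvalue"].clip(lower=1e-300)

    n_enr = int(round(config.frac_enriched_tss * len(tss)))
    enriched_ids = set(
        rng.choice(tss["feature_id"].to_numpy(), size=n_enr, replace=False)
    ) if n_enr else set()

    if n_v and enriched_ids:
        enr_pos = np.sort(
            tss.loc[tss["feature_id"].isin(enriched_ids), "tss_pos"].to_numpy()
        )
        pos0 = variants["pos"].to_numpy() - 1
        idx = np.searchsorted(enr_pos, pos0)
        dist = np.full(n_v, np.iinfo(np.int64).max, dtype=np.int64)
        for shift in (-1, 0):
            j = np.clip(idx + shift, 0, len(enr_pos) - 1)
            dist = np.minimum(dist, np.abs(pos0 - enr_pos[j]))
        near = dist <= config.placement_window
        thr = config.sig_p_threshold
        p_sig = min(1.0, config.enrichment_fold * thr)
        sig = rng.random(near.sum()) < p_sig
        new_p = np.where(
            sig,
            rng.uniform(0.0, thr, size=near.sum()),
            rng.uniform(thr, 1.0, size=near.sum()),
        )
        pv = variants["pvalue"].to_numpy()
        pv[near] = np.clip(new_p, 1e-300, 1.0)
        variants["pvalue"] = pv

    truth = SimTruth(
        enriched_tss_ids=enriched_ids,
        variant_sig_flag=pd.Series(
            variants["pvalue"].to_numpy() < config.sig_p_threshold,
            index=variants["variant_id"],
            name="significant",
        ),
    )
    return variants, truth


# ---------------------------------------------------------------------------
# motif data

def gen_motif_data(
    config: SimConfig, samples: pd.DataFrame
) -> tuple[pd.DataFrame, ExpressionTable, SimTruth]:
    """Sparse motif-count matrix N and expression generated from planted
    smooth motif activities: log2 expression = baseline + N_std A + noise.

    ``samples`` is a design table whose sample_id order defines the activity
    curves' sample axis.
    """
    rng = np.random.default_rng([config.seed, 4])
    n_f, n_m = config.n_features, config.n_motifs
    if n_m > n_f:
        raise ConfigError(
            "n_motifs exceeds n_features: motif activities are unidentifiable"
        )
    sample_ids = samples["sample_id"].tolist()
    n_s = len(sample_ids)
    if "timepoint_minutes" in samples.columns and samples[
        "timepoint_minutes"
    ].notna().all():
        t = samples["timepoint_minutes"].to_numpy(dtype=float)
    else:
        t = np.arange(n_s, dtype=float)

    counts = rng.poisson(1.2, size=(n_f, n_m))
    for m in range(n_m):  # no all-zero motif column
        if counts[:, m].sum() == 0:
            counts[rng.integers(n_f), m] = 1

    # planted activities: random two-bump smooth curves, zero-sum per motif
    peaks = rng.uniform(t.min() + 30.0, t.max() * 0.6, size=(n_m, 2))
    signs = rng.choice([-1.0, 1.0], size=(n_m, 2))
    activity = np.zeros((n_m, n_s))
    for m in range(n_m):
        for b in range(2):
            activity[m] += signs[m, b] * _gamma_kernel(t, peaks[m, b], shape=3.0)
    activity -= activity.mean(axis=1, keepdims=True)
    rms = np.sqrt((activity ** 2).mean(axis=1, keepdims=True))
    activity /= np.maximum(rms, 1e-12)

    n_std = (counts - counts.mean(axis=0)) / np.maximum(counts.std(axis=0), 1e-12)
    base = 8.0 + rng.normal(0.0, 1.0, size=(n_f, 1))
    log_expr = base + n_std @ activity
    log_expr += rng.normal(0.0, config.mara_noise_sd, size=log_expr.shape)
    tpm = np.maximum(np.exp2(log_expr) - 1.0, 0.0)

    feature_ids = [f"p{i:05d}" for i in range(n_f)]
    motif_ids = [f"M{m:03d}" for m in range(n_m)]
    motif_counts = pd.DataFrame(counts, index=feature_ids, columns=motif_ids)
    expr = ExpressionTable(
        pd.DataFrame(tpm, index=feature_ids, columns=sample_ids), unit="tpm"
    )
    truth = SimTruth(
        planted_activity=pd.DataFrame(activity, index=motif_ids, columns=sample_ids)
    )
    return motif_counts, expr, truth


# ---------------------------------------------------------------------------
# enhancer-promoter pairs

_PROMOTER_PEAKS = (240, 300, 360, 420, 480)


def gen_enhancer_promoter_pairs(
    config: SimConfig,
) -> tuple[pd.DataFrame, TimeCourseTensor, SimTruth]:
    """Paired transient profiles where each enhancer's kernel peaks
    ``enhancer_lead_minutes`` before its promoter's, plus loci placing the
    enhancer within +/-500 kb of the promoter TSS."""
    rng = np.random.default_rng([config.seed, 5])
    t = np.asarray(config.time_grid_minutes, dtype=float)
    grid_step = int(np.diff(t).min())
    lead = config.enhancer_lead_minutes
    if lead < grid_step:
        raise ConfigError(
            f"enhancer_lead_minutes={lead} below grid resolution {grid_step}"
        )
    n_pairs = config.n_enhancers
    n_d = config.n_donors

    peaks_p = rng.choice(_PROMOTER_PEAKS, size=n_pairs)
    peaks_e = peaks_p - lead
    if (peaks_e <= 0).any():
        raise ConfigError("enhancer_lead_minutes leaves no room before promoter peak")

    prom_ids = [f"p{i:05d}" for i in range(n_pairs)]
    enh_ids = [f"e{i:05d}" for i in range(n_pairs)]
    scale_p = rng.lognormal(math.log(40.0), 0.5, size=n_pairs)
    scale_e = rng.lognormal(math.log(8.0), 0.5, size=n_pairs)

    # sharp transient bursts (gamma shape 8): induced promoters and eRNAs
    # rise and fall within a few hours, much steeper around the peak than
    # the broad expression waves of the archetype kernels
    n_t = len(t)
    mean = np.empty((2 * n_pairs, n_t))
    for i in range(n_pairs):
        mean[i] = 2.0 + scale_p[i] * _gamma_kernel(t, float(peaks_p[i]), shape=8.0)
        mean[n_pairs + i] = 1.0 + scale_e[i] * _gamma_kernel(
            t, float(peaks_e[i]), shape=8.0
        )

    donor_effect = _lognormal_factor(rng, config.donor_effect_cv, (2 * n_pairs, 1, n_d))
    cell_noise = _lognormal_factor(rng, config.donor_noise_cv, (2 * n_pairs, n_t, n_d))
    expected = mean[:, :, None] * donor_effect * cell_noise
    values = _observe(rng, expected, config)

    donors = [f"donor{d + 1}" for d in range(n_d)]
    tensor = TimeCourseTensor(prom_ids + enh_ids, t, donors, values)

    tss = rng.integers(600_000, config.genome_length - 600_000, size=n_pairs)
    offsets = rng.integers(5_000, 500_001, size=n_pairs) * rng.choice(
        [-1, 1], size=n_pairs
    )
    strands = rng.choice(["+", "-"], size=n_pairs)
    loci = pd.DataFrame(
        {
            "feature_id": prom_ids + enh_ids,
            "chrom": "chr1",
            "tss_pos": np.concatenate([tss, tss + offsets]),
            "strand": np.concatenate([strands, np.full(n_pairs, ".")]),
            "feature_class": ["promoter"] * n_pairs + ["enhancer"] * n_pairs,
        }
    )
    pairs = pd.DataFrame(
        {
            "enhancer_id": enh_ids,
            "promoter_id": prom_ids,
            "lead_minutes": (peaks_p - peaks_e).astype(int),
        }
    )
    truth = SimTruth(pairs=pairs)
    return loci, tensor, truth
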