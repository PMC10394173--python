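"""Synthetic cohort and CT-phantom generators with planted, recorded effects.

These generators define the study conditions for every downstream stage:
log-normal bulk expression with TLS-marker upregulation in a TLS-high
subgroup, a GISTIC-style copy-number matrix with a deletion locus enriched
in TLS-low tumors plus planted TLS x CNA interaction genes, exponential
proportional-hazards survival with a protective TLS effect, and textured
ellipsoidal CT phantoms whose gray-level statistics depend on TLS status.

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs.  Truth records carry all planted gene ids and betas
so downstream screens can be scored for sensitivity/FDR without re-deriving
the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SimulationConfig",
    "PhantomConfig",
    "MaskedVolume",
    "simulate_expression",
    "simulate_cna_survival",
    "simulate_ct_phantom",
]

# Background GISTIC copy-number state frequencies {-2,-1,0,1,2}; chosen to
# resemble a copy-number-driven tumor with mostly neutral genes.
_GISTIC_STATES = np.array([-2, -1, 0, 1, 2])
_GISTIC_PROBS = np.array([0.02, 0.13, 0.70, 0.13, 0.02])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic transcriptomic/genomic/clinical cohort.

    marker_effect is the log2 fold-change added to every TLS-marker gene in
    TLS-high samples.  beta_tls is the log-hazard per unit of the z-scored
    TLS score (ln 0.55 matches the protective effect reported for the real
    cohorts); beta_interaction the log-hazard of each planted TLS x CNA
    interaction term.
    """

    n_samples: int = 300
    n_genes: int = 1000
    tls_fraction: float = 0.25
    marker_effect: float = 2.0
    marker_sample_sd: float = 1.0  # per-sample TLS-abundance heterogeneity
    planted_locus_genes: list[str] = field(default_factory=list)
    deletion_prob_low: float = 0.8
    deletion_prob_high: float = 0.1
    n_interaction_genes: int = 0
    beta_tls: float = float(np.log(0.55))
    beta_cna: float = 0.0
    beta_interaction: float = 0.0
    censor_fraction: float = 0.3
    baseline_hazard: float = 0.02  # events per month
    seed: int = 0

    def __post_init__(self):
        for name in ("tls_fraction", "deletion_prob_low", "deletion_prob_high"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0,1)")
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        for name in ("beta_tls", "beta_cna", "beta_interaction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class PhantomConfig:
    """Geometry and texture of the synthetic CT tumor phantom.

    The tumor interior is hu_tumor_mean plus a Gaussian random field whose
    correlation length (mm) and standard deviation (HU) depend on the TLS
    label; the exterior is homogeneous background.
    """

    shape: tuple[int, int, int] = (24, 24, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)  # mm, (x, y, z)
    hu_background: float = -50.0
    hu_tumor_mean: float = 40.0
    radius_fraction: float = 0.4  # ellipsoid semi-axes as fraction of extent
    texture_corr_length_high: float = 1.0   # mm
    texture_corr_length_low: float = 4.0
    texture_sd_high: float = 60.0           # HU
    texture_sd_low: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(d < 4 for d in self.shape):
            raise ValueError("volume too small for a tumor phantom")
        if not 0 < self.radius_fraction < 0.5:
            raise ValueError("radius_fraction must keep the tumor inside the volume")


@dataclass
class MaskedVolume:
    """3D scalar image (HU) + binary mask + voxel spacing in mm (x, y, z)."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.intensities.shape} != mask shape {self.mask.shape}"
            )
        if self.intensities.ndim != 3:
            raise ValueError("volume must be 3D")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)


def _sample_ids(n):
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _tls_labels(config: SimulationConfig) -> np.ndarray:
    n_high = int(round(config.tls_fraction * config.n_samples))
    if n_high < 1 or n_high >= config.n_samples:
        raise ValueError(
            f"degenerate design: tls_fraction={config.tls_fraction} gives "
            f"{n_high} TLS-high of {config.n_samples} samples"
        )
    labels = np.zeros(config.n_samples, dtype=int)
    labels[:n_high] = 1
    return labels


def simulate_expression(
    config: SimulationConfig,
    markers: list[str],
    background_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a log2 expression matrix (genes x samples) with TLS labels.

    Marker genes gain ``marker_effect`` log2 units of mean expression in
    TLS-high samples; all other genes are exchangeable between groups.
    ``background_genes`` names extra effect-free genes to include in the
    universe (e.g. markers of other immune populations).

    Returns (expression DataFrame indexed by gene id, label Series indexed
    by sample id with 1 = TLS-high).
    """
    rng = np.random.default_rng(config.seed)
    markers = list(markers)
    named = markers + [g for g in (background_genes or []) if g not in markers]
    n_extra = config.n_genes - len(named)
    if n_extra < 0:
        raise ValueError("n_genes smaller than the named gene list")
    genes = named + [f"G{i:05d}" for i in range(1, n_extra + 1)]
    samples = _sample_ids(config.n_samples)
    labels = _tls_labels(config)

    base = rng.normal(6.0, 1.5, size=len(genes))  # per-gene baseline log2 mean
    expr = base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), len(samples)))
    # TLS content varies continuously between patients: every marker gene
    # shares a per-sample abundance factor, keeping the signature score
    # continuous rather than cleanly bimodal.  Group means still differ by
    # exactly marker_effect.
    tls_abundance = config.marker_effect * labels + config.marker_sample_sd * rng.standard_normal(len(samples))
    expr[: len(markers), :] += tls_abundance[None, :]

    mat = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    return mat, pd.Series(labels, index=samples, name="tls_label")


def _calibrate_censoring(t_event: np.ndarray, u: np.ndarray, frac: float) -> np.ndarray:
    """Uniform(0, c_max) administrative censoring; c_max bisected so the
    realized censoring fraction matches ``frac`` as closely as the fixed
    uniform draws allow."""
    if frac == 0:
        return np.full_like(t_event, np.inf)

    def realized(c_max):
        return float(np.mean(c_max * u < t_event))

    lo, hi = 1e-6, float(t_event.max()) / max(u.min(), 1e-9) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) > frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) * u


def simulate_cna_survival(
    config: SimulationConfig,
    tls_scores: pd.Series,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the gene-level CNA matrix, clinical table, and truth record.

    Survival times follow an exponential baseline with log-hazard

        beta_tls * z(TLS) + sum_planted(beta_cna * CNA_g
                                        + beta_interaction * z(TLS) * CNA_g)

    Planted locus genes take value -1 with probability deletion_prob_low in
    TLS-low samples and deletion_prob_high in TLS-high samples.  Interaction
    genes carry background GISTIC values but contribute the interaction term
    to the hazard.  Censoring is uniform administrative, calibrated so the
    censored fraction hits the requested value within +-0.05.

    ``genes`` fixes the CNA gene universe (e.g. to the expression matrix's
    index so the two share ids); planted locus genes must then belong to
    it, and interaction genes are drawn deterministically from its tail.
    By default a fresh universe of locus + interaction + background ids is
    built from the config counts.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = list(tls_scores.index)
    n = len(samples)
    labels = _tls_labels(config)[:n] if n == config.n_samples else None
    if labels is None:
        raise ValueError("tls_scores must be aligned with config.n_samples samples")

    locus = list(config.planted_locus_genes)
    if genes is None:
        inter = [f"INT{i:03d}" for i in range(1, config.n_interaction_genes + 1)]
        n_bg = config.n_genes - len(locus) - len(inter)
        if n_bg < 0:
            raise ValueError("n_genes too small for the planted genes")
        genes = locus + inter + [f"C{i:05d}" for i in range(1, n_bg + 1)]
    else:
        genes = list(genes)
        missing = [g for g in locus if g not in genes]
        if missing:
            raise ValueError(f"planted locus genes not in the gene universe: {missing}")
        pool = [g for g in reversed(genes) if g not in locus]
        if len(pool) < config.n_interaction_genes:
            raise ValueError("gene universe too small for the interaction genes")
        inter = pool[: config.n_interaction_genes]

    locus_idx = [genes.index(g) for g in locus]
    inter_idx = [genes.index(g) for g in inter]
    cna = rng.choice(_GISTIC_STATES, size=(len(genes), n), p=_GISTIC_PROBS)
    for k in locus_idx:
        p_del = np.where(labels == 1, config.deletion_prob_high, config.deletion_prob_low)
        cna[k, :] = np.where(rng.random(n) < p_del, -1, 0)

    z = (tls_scores.to_numpy() - tls_scores.mean()) / tls_scores.std(ddof=0)
    eta = config.beta_tls * z
    for k in inter_idx:
        row = cna[k, :].astype(float)
        eta = eta + config.beta_cna * row + config.beta_interaction * z * row

    t_event = rng.exponential(1.0, size=n) / (config.baseline_hazard * np.exp(eta))
    c = _calibrate_censoring(t_event, rng.random(n), config.censor_fraction)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time_months": time,
            "event": event,
            "age_years": rng.normal(62, 10, size=n).round(1),
            "stage": rng.choice([1, 2, 3, 4], size=n, p=[0.05, 0.08, 0.6, 0.27]),
            "residual_disease": rng.choice([0, 1], size=n, p=[0.72, 0.28]),
            "tls_label": labels,
        }
    ).set_index("sample_id")

    cna_df = pd.DataFrame(cna, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = {
        "planted_locus_genes": locus,
        "interaction_genes": inter,
        "beta_tls": config.beta_tls,
        "beta_cna": config.beta_cna,
        "beta_interaction": config.beta_interaction,
        "tls_z": dict(zip(samples, z.tolist())),
    }
    return cna_df, clinical, truth


def couple_expression_to_cna(
    expr: pd.DataFrame, cna: pd.DataFrame, coefficient: float = 0.8,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Add a gene-dosage effect: expression += coefficient * own CNA.

    Applied to the shared genes (or the subset given), emulating the
    CNA-driven expression changes that make a screen hit a plausible
    cancer driver (positive CNA-expression correlation).
    """
    shared = [g for g in (genes if genes is not None else cna.index) if g in expr.index]
    out = expr.copy()
    cols = [s for s in expr.columns if s in cna.columns]
    out.loc[shared, cols] = (
        expr.loc[shared, cols] + coefficient * cna.loc[shared, cols].astype(float)
    )
    return out


def simulate_ct_phantom(config: PhantomConfig, tls_label: int) -> MaskedVolume:
    """Generate one textured ellipsoidal tumor phantom.

    The interior is hu_tumor_mean plus a smoothed Gaussian field (white
    noise convolved with a Gaussian kernel whose sigma equals the requested
    correlation length), rescaled so the in-mask SD equals the requested
    texture SD.  texture_sd = 0 yields an exactly constant interior.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    spacing = np.asarray(config.spacing, dtype=float)

    coords = np.meshgrid(*[np.arange(d) for d in shape], indexing="ij")
    center = [(d - 1) / 2 for d in shape]
    semi = [config.radius_fraction * d for d in shape]
    r2 = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi))
    mask = r2 <= 1.0
    if not mask.any():
        raise ValueError("tumor ellipsoid does not fit inside the volume")

    vol = np.full(shape, config.hu_background, dtype=float)
    vol[mask] = config.hu_tumor_mean

    corr = config.texture_corr_length_high if tls_label else config.texture_corr_length_low
    sd = config.texture_sd_high if tls_label else config.texture_sd_low
    if sd > 0:
        noise = rng.standard_normal(shape)
        sigma_vox = corr / spacing  # mm -> voxels per axis
        field_ = gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
        interior = field_[mask]
        s = interior.std()
        if s > 0:
            vol[mask] = config.hu_tumor_mean + (interior - interior.mean()) * (sd / s)

    return MaskedVolume(intensities=vol, mask=mask, spacing=tuple(spacing))
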