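"""Synthetic study generator with known ground truth.

Emulates every input the analysis pipeline consumes:

* a spherical parcellation (deterministic Fibonacci lattice per hemisphere,
  mirror-symmetric in x) standing in for FreeSurfer sphere centroids;
* donor-level regional expression built from a planted two-component
  low-rank structure, per-gene baselines, an additive hemisphere offset
  artifact (default 0.056 log2 units, the observed left-right mean gap) and
  donor noise, summarised to a cross-donor median matrix;
* optional "specific" genes whose profiles are orthogonal to the planted
  components and instead share a common spatial core -- the co-expression
  structure one expects of genes that all track the same regional phenotype;
* multi-cohort cognitive batteries with a latent g, within-domain residual
  covariance and optional MCAR missingness;
* regional morphometry whose true g-association map combines a quadratic
  function of the planted component scores (strongest associations where
  scores are balanced near 0), the specific-gene core, and spatially
  uncorrelated noise.

The defaults are the study-scale conditions (68 paired regions, planted
two-component variance fraction 0.5, batteries loading ~0.7 on g);
generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import DonorProfiles, scale_by_hemisphere
from .errors import InvalidParameterError

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Standardized composition of the true g-association maps: per-measure
#: weight of the component-balance (quadratic) term, echoing the relative
#: strength of the observed component associations per measure, plus the
#: observed per-measure mean/SD used to place the maps on the beta scale.
BETA_MAP_DEFAULTS = {
    "volume": {"mean": 0.103, "sd": 0.034, "quad_weight": -0.55},
    "surface_area": {"mean": 0.102, "sd": 0.027, "quad_weight": -0.50},
    "thickness": {"mean": 0.031, "sd": 0.035, "quad_weight": -0.25},
}

#: Variance share of measure-specific spatially uncorrelated map noise.
MAP_NOISE_VAR = 0.05

#: Reference specific-core weight: the volume map's core weight, used to
#: convert a nominal gene effect into a gene-core correlation.
GAMMA_REF = float(
    np.sqrt(1.0 - BETA_MAP_DEFAULTS["volume"]["quad_weight"] ** 2 - MAP_NOISE_VAR)
)


# ---------------------------------------------------------------------------
# parcellation

def generate_sphere_parcellation(
    n_per_hemisphere: int, seed: int = 0
) -> pd.DataFrame:
    """Unit-sphere parcel centroids, mirror-symmetric across hemispheres.

    Points are a Fibonacci lattice on the right half-sphere (x > 0), rotated
    about the x axis by a seed-derived angle; left centroids are the x-mirror
    of the right ones.  Deterministic for a fixed seed.
    """
    if n_per_hemisphere < 3:
        raise InvalidParameterError("need at least 3 regions per hemisphere")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0, 2 * np.pi)
    i = np.arange(n_per_hemisphere)
    x = (i + 0.5) / n_per_hemisphere  # in (0, 1): right half-sphere
    r = np.sqrt(1 - x**2)
    theta = GOLDEN_ANGLE * i + angle
    y = r * np.cos(theta)
    z = r * np.sin(theta)
    rows = []
    for h, sign in (("lh", -1.0), ("rh", 1.0)):
        for j in range(n_per_hemisphere):
            rows.append(
                {
                    "region": f"{h}_region{j + 1:02d}",
                    "hemisphere": h,
                    "x": sign * x[j],
                    "y": y[j],
                    "z": z[j],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionParams:
    """Generative settings for donor-level regional expression."""

    variance_fraction: float = 0.5  # share of standardized variance planted
    hemisphere_offset: float = 0.056  # log2 units added to the left hemisphere
    donor_noise_sd: float = 0.1
    gene_mean_loc: float = 6.06  # log2-intensity baseline
    gene_mean_scale: float = 2.35
    score_pair_rho: float = 0.85  # target left/right score correlation
    #: RMS loading per component; the ~1.8:1 variance ratio keeps the two
    #: components separable by an unrotated decomposition
    loading_scales: tuple = (0.58, 0.43)
    n_planted_genes: int = 0  # strong specific genes
    planted_effect: float = 0.4  # nominal standardized coefficient on the map
    background_frac: float = 0.0  # share of genes with weak specific effects
    background_effect_range: tuple = (0.2, 0.7)


@dataclass
class ExpressionTruth:
    """Planted quantities behind a generated expression dataset."""

    true_loadings: pd.DataFrame  # genes x 2
    true_scores: pd.DataFrame  # regions x 2, z-scaled per hemisphere
    hemisphere_offset: float
    donor_noise_sd: float
    gene_mean: pd.Series
    planted_genes: list = field(default_factory=list)
    background_genes: list = field(default_factory=list)
    gene_effects: pd.Series | None = None  # nominal signed effects, all specific
    specific_core: pd.Series | None = None  # shared spatial core of specific genes
    planted_effect: float = 0.0


def _orthogonal_hemisphere_scores(
    n_regions: int, region_ids, rho: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Two score columns, orthogonal overall and z-scaled per hemisphere,
    with paired left/right values correlated by construction.

    Alternating projections between the two constraints (column
    orthogonality; per-hemisphere standardization) converge quickly.
    """
    half = n_regions // 2
    base = rng.normal(size=(half, 2))
    right = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=(half, 2))
    scores = np.vstack([base, right])
    ids = pd.Index(region_ids)
    for _ in range(200):
        # orthogonalize columns
        q, _ = np.linalg.qr(scores - scores.mean(axis=0))
        scores = q * np.sqrt(n_regions - 1)
        # per-hemisphere standardization
        scores = scale_by_hemisphere(scores, region_ids=ids)
        off = scores[:, 0] @ scores[:, 1]
        if abs(off) < 1e-10:
            break
    return pd.DataFrame(scores, index=ids, columns=["C1", "C2"])


def _component_orthogonal_vector(
    scores: np.ndarray, region_ids, rng: np.random.Generator
) -> np.ndarray:
    """A hemisphere-scaled regional pattern orthogonal to both score maps."""
    n = scores.shape[0]
    v = rng.normal(size=n)
    basis = np.column_stack([np.ones(n), scores])
    q, _ = np.linalg.qr(basis)
    v = v - q @ (q.T @ v)
    v = scale_by_hemisphere(v, region_ids=region_ids)
    # re-project: hemisphere scaling only nudges the overlap slightly
    v = v - q @ (q.T @ v)
    return v / v.std(ddof=1)


def generate_expression(
    n_regions: int = 68,
    n_genes: int = 2000,
    n_donors: int = 6,
    params: ExpressionParams | None = None,
    seed: int = 0,
):
    """Generate donor matrices, their median matrix and the planted truth.

    Returns ``(profiles, median_matrix, truth)`` where ``profiles`` is a
    :class:`cogex.atlas.DonorProfiles`.  Bulk genes carry the planted
    two-component structure with per-gene residual noise set so the
    components account for ``variance_fraction`` of each gene's standardized
    variance.  Specific genes (candidates and background, if requested)
    instead carry ``sqrt(rho) * core + sqrt(1 - rho) * white`` where ``rho``
    is derived from the gene's nominal map effect, so the *observed* profile
    correlates with the shared core at the planted strength.  The hemisphere
    offset is added to raw left-hemisphere values.
    """
    if n_regions % 2:
        raise InvalidParameterError("n_regions must be even (paired hemispheres)")
    if n_genes < 10:
        raise InvalidParameterError("n_genes must be >= 10")
    if n_donors < 1:
        raise InvalidParameterError("n_donors must be >= 1")
    p = params or ExpressionParams()
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    region_ids = pd.Index(
        [f"lh_region{j + 1:02d}" for j in range(half)]
        + [f"rh_region{j + 1:02d}" for j in range(half)]
    )
    gene_ids = pd.Index([f"gene{j + 1:05d}" for j in range(n_genes)])

    scores = _orthogonal_hemisphere_scores(n_regions, region_ids,
                                           p.score_pair_rho, rng)
    T = scores.to_numpy()

    loadings = rng.normal(size=(n_genes, 2)) * np.asarray(p.loading_scales)
    gene_mean = rng.normal(p.gene_mean_loc, p.gene_mean_scale, size=n_genes)

    n_bg = int(round(p.background_frac * n_genes))
    n_cand = p.n_planted_genes
    if n_cand + n_bg >= n_genes:
        raise InvalidParameterError("too many specific genes for n_genes")
    cand_idx = np.arange(n_genes - n_cand, n_genes)
    bg_idx = np.arange(n_genes - n_cand - n_bg, n_genes - n_cand)
    specific_idx = np.concatenate([bg_idx, cand_idx])

    effects = np.zeros(n_genes)
    core = None
    if specific_idx.size:
        core = _component_orthogonal_vector(T, region_ids, rng)
        lo, hi = p.background_effect_range
        effects[bg_idx] = rng.uniform(lo, hi, size=n_bg) * rng.choice(
            [-1.0, 1.0], size=n_bg
        )
        effects[cand_idx] = p.planted_effect

    signal = T @ loadings.T  # regions x genes
    sig_var = signal.var(axis=0)
    frac = p.variance_fraction
    noise_sd = np.sqrt(np.clip(sig_var, 1e-12, None) * (1 - frac) / frac)

    if specific_idx.size:
        # specific genes: profile reliability is folded into the planted
        # correlation with the core, at a bulk-comparable amplitude
        amp = float(np.sqrt((signal.var(axis=0) + noise_sd**2).mean()))
        loadings[specific_idx] = 0.0
        for g in specific_idx:
            rho = min((effects[g] / GAMMA_REF) ** 2, 0.95)
            unique = rng.normal(size=n_regions)
            profile = np.sign(effects[g]) * np.sqrt(rho) * core + np.sqrt(
                1 - rho
            ) * unique / unique.std(ddof=1)
            signal[:, g] = amp * profile
        noise_sd[specific_idx] = 0.0

    base = gene_mean[None, :] + signal
    base = base + rng.normal(size=(n_regions, n_genes)) * noise_sd[None, :]
    left_mask = np.char.startswith(region_ids.to_numpy().astype(str), "lh_")
    base[left_mask] += p.hemisphere_offset

    donors = {}
    stack = np.empty((n_donors, n_regions, n_genes))
    for d in range(n_donors):
        noise = (
            rng.normal(size=(n_regions, n_genes)) * p.donor_noise_sd
            if p.donor_noise_sd > 0
            else 0.0
        )
        mat = base + noise
        stack[d] = mat
        donors[f"donor{d + 1}"] = pd.DataFrame(
            mat, index=region_ids, columns=gene_ids
        )
    median = pd.DataFrame(
        np.median(stack, axis=0), index=region_ids, columns=gene_ids
    )
    # truth loadings on the gene-component correlation scale (scores are
    # unit-variance, so corr = raw loading / total per-gene SD)
    total_sd = np.sqrt(signal.var(axis=0) + noise_sd**2)
    total_sd[total_sd == 0] = 1.0
    loadings_corr = loadings / total_sd[:, None]
    truth = ExpressionTruth(
        true_loadings=pd.DataFrame(loadings_corr, index=gene_ids,
                                   columns=["C1", "C2"]),
        true_scores=scores,
        hemisphere_offset=p.hemisphere_offset,
        donor_noise_sd=p.donor_noise_sd,
        gene_mean=pd.Series(gene_mean, index=gene_ids, name="gene_mean"),
        planted_genes=[gene_ids[i] for i in cand_idx],
        background_genes=[gene_ids[i] for i in bg_idx],
        gene_effects=pd.Series(effects, index=gene_ids, name="effect"),
        specific_core=(
            pd.Series(core, index=region_ids, name="core")
            if core is not None
            else None
        ),
        planted_effect=p.planted_effect if n_cand else 0.0,
    )
    return DonorProfiles(donors=donors), median, truth


# ---------------------------------------------------------------------------
# beta maps and cohorts

def make_beta_maps(
    truth: ExpressionTruth,
    measures=("volume", "surface_area", "thickness"),
    map_params: dict | None = None,
    map_noise_var: float = MAP_NOISE_VAR,
    seed: int = 0,
) -> pd.DataFrame:
    """True regional g-association maps (regions x measures).

    On a standardized scale each map is quad_weight * z(s1^2 + s2^2) +
    gamma * core + noise, with gamma^2 = 1 - quad_weight^2 - noise variance,
    then placed on the beta scale using the measure's mean/SD.  With no
    specific genes the core term is absent and, at zero noise, the map is an
    exact quadratic in the true scores.
    """
    map_params = {**BETA_MAP_DEFAULTS, **(map_params or {})}
    rng = np.random.default_rng(seed)
    T = truth.true_scores.to_numpy()
    quad = (T**2).sum(axis=1)
    sdq = quad.std(ddof=1)
    quad_z = (quad - quad.mean()) / (sdq if sdq > 0 else 1.0)
    core = (
        truth.specific_core.to_numpy() if truth.specific_core is not None else None
    )
    cols = {}
    for m in measures:
        cfg = map_params[m]
        qw = cfg["quad_weight"]
        std_map = qw * quad_z
        if core is not None:
            gamma = np.sqrt(max(1.0 - qw**2 - map_noise_var, 0.0))
            std_map = std_map + gamma * core
        if map_noise_var > 0:
            std_map = std_map + rng.normal(
                scale=np.sqrt(map_noise_var), size=len(quad_z)
            )
        sd = std_map.std(ddof=1)
        cols[m] = cfg["mean"] + cfg["sd"] * (std_map - std_map.mean()) / (
            sd if sd > 0 else 1.0
        )
    return pd.DataFrame(cols, index=truth.true_scores.index)


@dataclass
class CohortParams:
    """Generative settings for one cohort's battery and morphometry."""

    loading: float | np.ndarray = 0.7  # test loadings on g, in (0, 1)
    n_domains: int = 4
    domain_resid_sd: float = 0.25  # within-domain shared residual SD
    missing_rate: float = 0.0  # MCAR on cognitive tests
    age_range: tuple = (44.0, 83.0)
    n_sites: int = 2
    test_age_beta: float = 0.1  # standardized age effect on each test
    test_sex_beta: float = 0.1
    covariate_beta: float = 0.1  # standardized covariate effect on morphometry
    with_lag: bool = False


@dataclass
class CohortTruth:
    """Planted quantities behind a generated cohort."""

    g_true: pd.Series
    test_loadings: pd.Series
    domain_labels: pd.Series
    residual_cov: dict
    beta_map_true: pd.DataFrame  # regions x measures
    planted_genes: list = field(default_factory=list)
    planted_effect: float = 0.0


def generate_cohort(
    n_participants: int,
    n_tests: int,
    beta_maps: pd.DataFrame,
    params: CohortParams | None = None,
    planted_genes=None,
    planted_effect: float = 0.0,
    seed: int = 0,
    cohort: str = "cohort",
):
    """Generate one cohort's phenotype table and its ground truth.

    Tests are lambda*g + within-domain shared residual + unique noise (unit
    total variance before age/sex effects); regional morphometry is
    beta_true[r, m]*g + covariate effects + noise on a standardized scale.
    """
    if n_tests < 3:
        raise InvalidParameterError("need at least 3 tests for identifiability")
    p = params or CohortParams()
    lam = np.broadcast_to(np.asarray(p.loading, dtype=float), (n_tests,)).copy()
    if np.any((lam < 0) | (lam >= 1)):
        raise InvalidParameterError("test loadings must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_participants

    g = rng.normal(size=n)
    age = rng.uniform(*p.age_range, size=n)
    age_z = (age - age.mean()) / age.std(ddof=1)
    sex = rng.integers(0, 2, size=n).astype(float)
    site = rng.integers(0, p.n_sites, size=n)
    head = rng.normal(size=(n, 3))

    domains = np.arange(n_tests) % p.n_domains
    domain_factors = rng.normal(size=(n, p.n_domains))
    d_sd = p.domain_resid_sd
    columns: dict[str, np.ndarray] = {
        "cohort": np.repeat(cohort, n),
        "age": age,
        "sex": sex,
        "site": site,
        "head_x": head[:, 0],
        "head_y": head[:, 1],
        "head_z": head[:, 2],
    }
    if p.with_lag:
        columns["lag"] = rng.normal(65.0, 37.0, size=n).clip(0)
    test_names = []
    for j in range(n_tests):
        unique_var = max(1.0 - lam[j] ** 2 - d_sd**2, 1e-4)
        y = (
            lam[j] * g
            + d_sd * domain_factors[:, domains[j]]
            + np.sqrt(unique_var) * rng.normal(size=n)
            + p.test_age_beta * age_z
            + p.test_sex_beta * (sex - 0.5)
        )
        if p.missing_rate > 0:
            y = np.where(rng.random(n) < p.missing_rate, np.nan, y)
        name = f"test{j + 1:02d}"
        test_names.append(name)
        columns[name] = y

    c = p.covariate_beta
    covar_effect = c * (
        age_z + (sex - 0.5) + head.sum(axis=1) + (site - site.mean())
    )
    covar_var = covar_effect.var()
    for measure in beta_maps.columns:
        for region, b in beta_maps[measure].items():
            noise_var = max(1.0 - b**2 - covar_var, 0.1)
            columns[f"{measure}__{region}"] = (
                b * g + covar_effect + np.sqrt(noise_var) * rng.normal(size=n)
            )
    frame = pd.DataFrame(columns)

    truth = CohortTruth(
        g_true=pd.Series(g, name="g_true"),
        test_loadings=pd.Series(lam, index=test_names, name="lambda"),
        domain_labels=pd.Series(
            [f"domain{d + 1}" for d in domains], index=test_names, name="domain"
        ),
        residual_cov={"domain_resid_sd": d_sd},
        beta_map_true=beta_maps,
        planted_genes=list(planted_genes or []),
        planted_effect=planted_effect,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# cell-type map and writers

def generate_cell_map(
    gene_ids, n_types: int = 9, genes_per_type: int = 20, seed: int = 0
) -> pd.Series:
    """Random gene -> cell-type assignment; unassigned genes are unclassified."""
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index(gene_ids)
    chosen = rng.choice(len(gene_ids), size=n_types * genes_per_type,
                        replace=False)
    labels = {}
    names = [f"celltype{t + 1}" for t in range(n_types)]
    for t, name in enumerate(names):
        for i in chosen[t * genes_per_type : (t + 1) * genes_per_type]:
            labels[gene_ids[i]] = name
    return pd.Series(labels, name="cell_type")


def write_truth_json(truth, path) -> None:
    """Serialize a truth dataclass (frames as split-orient dicts) to JSON."""

    def convert(obj):
        if isinstance(obj, (pd.DataFrame, pd.Series)):
            return json.loads(obj.to_json(orient="split"))
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump({k: convert(v) for k, v in asdict(truth).items()}, fh,
                  indent=1, default=str)
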