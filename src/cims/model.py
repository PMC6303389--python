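"""Causal-inference model of audiovisual syllable perception.

The McGurk effect -- hearing "ba" while watching a talker mouth "ga" and
perceiving the fused syllable "da" -- is modeled here as Bayesian causal
inference in a two-dimensional representational space, with the auditory
speech feature on the x-axis and the visual speech feature on the y-axis.
Perception proceeds in four linked stages:

1. **Encoding.** Each modality's token is encoded as the syllable prototype
   location plus zero-mean Gaussian noise with a modality-specific
   covariance. Audition is precise along the auditory axis, vision along the
   visual axis.
2. **Integration.** The two encodings are fused by precision weighting
   (Bayes-optimal under a single cause), yielding an integrated location
   whose covariance is smaller than either input.
3. **Causal inference.** The observer computes the posterior probability
   that the auditory and visual streams share a common cause (one talker,
   C = 1) versus separate causes (C = 2). On the log-odds scale the prior is
   augmented by temporal-synchrony evidence that grows linearly with the
   number of co-articulated repetitions, and diminished by a quadratic
   penalty on the encoded audiovisual content disparity. Repetition without
   co-articulation contributes no extra synchrony evidence.
4. **Decision.** The final representation is the model average of the
   integrated location (weight = posterior probability of a common cause)
   and the auditory-only location (audition being the most reliable
   unisensory cue for speech). A nearest-prototype rule -- equivalent to
   linear category boundaries -- maps it to a reported syllable.

All randomness flows through an explicit :class:`numpy.random.Generator`;
there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit, logit
from scipy.stats import multivariate_normal, norm

__all__ = [
    "CATEGORIES",
    "SyllablePrototype",
    "ModalityNoise",
    "CIMSParams",
    "StimulusSpec",
    "PerceptDistribution",
    "default_prototypes",
    "encode",
    "integrate",
    "common_cause_posterior",
    "causal_inference_combine",
    "classify",
    "classify_many",
    "predict_percept_distribution",
    "gaussian_percept_distribution",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

#: Response categories, in tie-break priority order (auditory-consistent
#: category first; ties are measure-zero under continuous noise but the
#: rule must be deterministic).
CATEGORIES: tuple[str, str, str] = ("ba", "da", "ga")


# ---------------------------------------------------------------------------
# small linear-algebra helpers
# ---------------------------------------------------------------------------

def _as_point(x, name: str = "location") -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.shape != (2,):
        raise ValueError(f"{name} must be a length-2 feature coordinate, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} must be finite")
    return p


def _as_cov(m, name: str = "covariance") -> np.ndarray:
    c = np.asarray(m, dtype=float)
    if c.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got shape {c.shape}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite")
    return c


def _sqrt_psd(c: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root of a PSD matrix (handles exact zeros)."""
    w, u = np.linalg.eigh(c)
    return (u * np.sqrt(np.clip(w, 0.0, None))) @ u.T


def _inv_pd(c: np.ndarray, name: str = "covariance") -> np.ndarray:
    try:
        l = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is singular; a positive-definite matrix is required") from exc
    linv = np.linalg.inv(l)
    return linv.T @ linv


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyllablePrototype:
    """A labeled location in the auditory x visual feature plane."""

    label: str
    location: tuple[float, float]

    def __post_init__(self) -> None:
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown syllable label {self.label!r}; expected one of {CATEGORIES}")
        object.__setattr__(self, "location", tuple(_as_point(self.location)))


def default_prototypes() -> dict[str, np.ndarray]:
    """Canonical tripartite map on the unit square.

    "da" sits midway between "ba" and "ga" on both axes, so the linear
    category boundaries are the two parallel lines x + y = 0.5 and
    x + y = 1.5.
    """
    return {
        "ba": np.array([0.0, 0.0]),
        "da": np.array([0.5, 0.5]),
        "ga": np.array([1.0, 1.0]),
    }


def validate_prototypes(prototypes) -> dict[str, np.ndarray]:
    """Normalize and validate a prototype set.

    Accepts a mapping label -> location or an iterable of
    :class:`SyllablePrototype`. Requires all three labels exactly once and
    "da" strictly between "ba" and "ga" on both axes.
    """
    if isinstance(prototypes, Mapping):
        items = {str(k): _as_point(v, f"prototype {k!r}") for k, v in prototypes.items()}
    else:
        protos = list(prototypes)
        if any(not isinstance(p, SyllablePrototype) for p in protos):
            raise ValueError("prototypes must be a mapping or a sequence of SyllablePrototype")
        items = {p.label: np.asarray(p.location, dtype=float) for p in protos}
        if len(items) != len(protos):
            raise ValueError("duplicate prototype labels")
    if set(items) != set(CATEGORIES):
        raise ValueError(f"prototype labels must be exactly {set(CATEGORIES)}, got {set(items)}")
    ba, da, ga = items["ba"], items["da"], items["ga"]
    for axis in range(2):
        lo, hi = sorted((ba[axis], ga[axis]))
        if not (lo < da[axis] < hi):
            raise ValueError(
                "'da' prototype must lie strictly between 'ba' and 'ga' on both axes"
            )
    return items


@dataclass
class ModalityNoise:
    """Encoding-noise covariances for the two modalities.

    Defaults are axis-aligned with greater auditory precision along the
    auditory (x) axis and greater visual precision along the visual (y)
    axis. Zero (semidefinite) covariances are accepted to support
    noiseless limiting analyses; operations that require invertibility
    raise on singular input.
    """

    sigma_A: np.ndarray = field(default_factory=lambda: np.diag([0.02, 0.18]))
    sigma_V: np.ndarray = field(default_factory=lambda: np.diag([0.18, 0.02]))

    def __post_init__(self) -> None:
        self.sigma_A = _as_cov(self.sigma_A, "sigma_A")
        self.sigma_V = _as_cov(self.sigma_V, "sigma_V")

    def scaled(self, factor: float) -> "ModalityNoise":
        if factor < 0:
            raise ValueError("noise scale factor must be nonnegative")
        return ModalityNoise(self.sigma_A * factor, self.sigma_V * factor)


@dataclass
class CIMSParams:
    """Full parameterization of the causal-inference model.

    Parameters
    ----------
    prototypes
        Mapping label -> 2-D location (validated; "da" between "ba" and "ga").
    noise
        Modality-specific encoding covariances.
    prior_common
        Prior probability of a single talker before trial evidence, in
        [0, 1]. The open interval is the ordinary regime; the endpoints are
        accepted as degenerate limits (forced segregation / forced fusion).
    lambda_sync
        Log-odds evidence for a common cause contributed by temporal
        synchrony, per co-articulated repetition (>= 0).
    kappa_content
        Scale of the quadratic penalty that encoded audiovisual content
        disparity exerts against a common cause (>= 0).
    disparity_metric
        "euclidean" (default) or "mahalanobis" (whitened by
        sigma_A + sigma_V), the metric for the encoded disparity.
    """

    prototypes: dict[str, np.ndarray] = field(default_factory=default_prototypes)
    noise: ModalityNoise = field(default_factory=ModalityNoise)
    prior_common: float = 0.5
    lambda_sync: float = 0.35
    kappa_content: float = 0.8
    disparity_metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.prototypes = validate_prototypes(self.prototypes)
        if not isinstance(self.noise, ModalityNoise):
            raise ValueError("noise must be a ModalityNoise")
        if not (0.0 <= self.prior_common <= 1.0):
            raise ValueError("prior_common must lie in [0, 1]")
        if self.lambda_sync < 0:
            raise ValueError("lambda_sync must be nonnegative")
        if self.kappa_content < 0:
            raise ValueError("kappa_content must be nonnegative")
        if self.disparity_metric not in ("euclidean", "mahalanobis"):
            raise ValueError("disparity_metric must be 'euclidean' or 'mahalanobis'")


@dataclass(frozen=True)
class StimulusSpec:
    """One audiovisual stimulus: tokens, repetition count, co-articulation."""

    auditory_token: str
    visual_token: str
    n_repetitions: int = 1
    coarticulated: bool = False

    def __post_init__(self) -> None:
        for tok in (self.auditory_token, self.visual_token):
            if tok not in CATEGORIES:
                raise ValueError(f"unknown token {tok!r}; expected one of {CATEGORIES}")
        if int(self.n_repetitions) != self.n_repetitions or self.n_repetitions < 1:
            raise ValueError("n_repetitions must be an integer >= 1")
        object.__setattr__(self, "n_repetitions", int(self.n_repetitions))

    @property
    def is_mcgurk(self) -> bool:
        return self.auditory_token != self.visual_token


@dataclass(frozen=True)
class PerceptDistribution:
    """Predicted response probabilities over the three categories."""

    p_ba: float
    p_da: float
    p_ga: float

    def __post_init__(self) -> None:
        probs = self.as_array()
        if np.any(probs < -1e-12):
            raise ValueError("percept probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("percept probabilities must sum to 1 within 1e-9")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_ba, self.p_da, self.p_ga])

    def __getitem__(self, label: str) -> float:
        return dict(zip(CATEGORIES, self.as_array()))[label]


# ---------------------------------------------------------------------------
# stage 1: encoding
# ---------------------------------------------------------------------------

def encode(token: str, modality: str, params: CIMSParams, rng: np.random.Generator) -> np.ndarray:
    """Draw one noisy encoding of a token in the given modality.

    Returns the prototype location plus zero-mean Gaussian noise with the
    modality's covariance.
    """
    if token not in params.prototypes:
        raise ValueError(f"unknown token {token!r}")
    if modality == "auditory":
        cov = params.noise.sigma_A
    elif modality == "visual":
        cov = params.noise.sigma_V
    else:
        raise ValueError(f"modality must be 'auditory' or 'visual', got {modality!r}")
    mean = params.prototypes[token]
    return mean + _sqrt_psd(cov) @ rng.standard_normal(2)


def _encode_samples(mean: np.ndarray, cov: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return mean + rng.standard_normal((n, 2)) @ _sqrt_psd(cov).T


# ---------------------------------------------------------------------------
# stage 2: precision-weighted integration
# ---------------------------------------------------------------------------

def integrate(
    mu_A: np.ndarray,
    sigma_A: np.ndarray,
    mu_V: np.ndarray,
    sigma_V: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse two Gaussian cue representations by precision weighting.

    sigma_AV = (sigma_A^-1 + sigma_V^-1)^-1 and
    mu_AV = sigma_AV (sigma_A^-1 mu_A + sigma_V^-1 mu_V). The fused
    covariance is smaller than either input (both differences PSD).

    Raises
    ------
    ValueError
        If either covariance is singular.
    """
    mu_A = _as_point(mu_A, "mu_A")
    mu_V = _as_point(mu_V, "mu_V")
    prec_A = _inv_pd(_as_cov(sigma_A, "sigma_A"), "sigma_A")
    prec_V = _inv_pd(_as_cov(sigma_V, "sigma_V"), "sigma_V")
    sigma_AV = np.linalg.inv(prec_A + prec_V)
    sigma_AV = 0.5 * (sigma_AV + sigma_AV.T)
    mu_AV = sigma_AV @ (prec_A @ mu_A + prec_V @ mu_V)
    return mu_AV, sigma_AV


# ---------------------------------------------------------------------------
# stage 3: common-cause posterior
# ---------------------------------------------------------------------------

def _effective_repetitions(stimulus: StimulusSpec) -> int:
    """Repetitions that contribute synchrony evidence.

    Only co-articulated repetitions (a continuous speech stream) accumulate
    temporal-synchrony evidence; isolated repetitions count once.
    """
    return stimulus.n_repetitions if stimulus.coarticulated else 1


def common_cause_posterior(params: CIMSParams, stimulus: StimulusSpec, disparity: float) -> float:
    """Posterior probability that both streams come from one talker.

    log-odds(C=1) = logit(prior_common) + n_eff * lambda_sync
                    - kappa_content * disparity**2,
    with n_eff the number of co-articulated repetitions (1 if the stimulus
    is not co-articulated). The content-disparity penalty is fixed across
    repetitions while the synchrony evidence grows with them.
    """
    disparity = float(disparity)
    if not math.isfinite(disparity) or disparity < 0:
        raise ValueError("disparity must be a nonnegative real")
    if params.prior_common == 0.0:
        return 0.0
    if params.prior_common == 1.0:
        return 1.0
    log_odds = (
        logit(params.prior_common)
        + _effective_repetitions(stimulus) * params.lambda_sync
        - params.kappa_content * disparity**2
    )
    return float(expit(log_odds))


# ---------------------------------------------------------------------------
# stage 4a: model averaging
# ---------------------------------------------------------------------------

def causal_inference_combine(mu_AV: np.ndarray, mu_A: np.ndarray, p_common: float) -> np.ndarray:
    """Model-average the fused and auditory-only locations.

    Returns p_common * mu_AV + (1 - p_common) * mu_A: a point on the
    segment between the auditory representation (C = 2; audition is the
    most reliable unisensory cue for speech) and the integrated
    representation (C = 1).
    """
    p_common = float(p_common)
    if not (0.0 <= p_common <= 1.0):
        raise ValueError("p_common must lie in [0, 1]")
    return p_common * _as_point(mu_AV, "mu_AV") + (1.0 - p_common) * _as_point(mu_A, "mu_A")


# ---------------------------------------------------------------------------
# stage 4b: linear decision rule
# ---------------------------------------------------------------------------

def _prototype_matrix(prototypes: Mapping[str, np.ndarray]) -> np.ndarray:
    protos = validate_prototypes(prototypes)
    return np.stack([protos[c] for c in CATEGORIES])


def classify_many(locations: np.ndarray, prototypes: Mapping[str, np.ndarray]) -> np.ndarray:
    """Nearest-prototype labels for an (n, 2) array of locations.

    Ties are broken by the fixed category order ba > da > ga.
    """
    loc = np.atleast_2d(np.asarray(locations, dtype=float))
    if loc.shape[1] != 2:
        raise ValueError("locations must have shape (n, 2)")
    pmat = _prototype_matrix(prototypes)
    d2 = ((loc[:, None, :] - pmat[None, :, :]) ** 2).sum(axis=-1)
    # argmin returns the first minimum, which realizes the ba > da > ga tie rule
    return np.array(CATEGORIES)[np.argmin(d2, axis=1)]


def classify(location: np.ndarray, prototypes: Mapping[str, np.ndarray]) -> str:
    """Nearest-prototype label for a single location (linear boundaries)."""
    return str(classify_many(np.asarray(location, dtype=float)[None, :], prototypes)[0])


# ---------------------------------------------------------------------------
# full pipeline: Monte Carlo percept prediction
# ---------------------------------------------------------------------------

def _fusion_operators(sigma_A: np.ndarray, sigma_V: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision matrices and fused covariance, with a graceful zero-noise limit.

    Exactly singular covariances are regularized by eps*I so that the
    fusion weights take their natural limits (both zero -> equal weights,
    one zero -> that modality dominates). Positive-definite inputs are
    untouched.
    """
    def prep(c):
        if np.linalg.eigvalsh(c).min() <= 1e-12:
            c = c + 1e-10 * np.eye(2)
        return c
    a, v = prep(sigma_A), prep(sigma_V)
    prec_A = _inv_pd(a, "sigma_A")
    prec_V = _inv_pd(v, "sigma_V")
    s = np.linalg.inv(prec_A + prec_V)
    return prec_A, prec_V, 0.5 * (s + s.T)


def _disparity_sq(diff: np.ndarray, params: CIMSParams) -> np.ndarray:
    """Squared encoded disparity, rowwise, under the configured metric."""
    if params.disparity_metric == "euclidean":
        return (diff**2).sum(axis=1)
    total = params.noise.sigma_A + params.noise.sigma_V
    m = _inv_pd(total + 1e-12 * np.eye(2), "sigma_A + sigma_V")
    return np.einsum("ij,jk,ik->i", diff, m, diff)


def _simulate_category_counts(
    params: CIMSParams, stimulus: StimulusSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Counts over CATEGORIES from n Monte Carlo runs of the full pipeline."""
    mu_a = params.prototypes[stimulus.auditory_token]
    mu_v = params.prototypes[stimulus.visual_token]
    sig_a, sig_v = params.noise.sigma_A, params.noise.sigma_V
    a = _encode_samples(mu_a, sig_a, n, rng)
    v = _encode_samples(mu_v, sig_v, n, rng)

    if params.prior_common == 0.0:
        final = a
    else:
        prec_a, prec_v, s = _fusion_operators(sig_a, sig_v)
        mu_av = (a @ prec_a.T + v @ prec_v.T) @ s.T
        if params.prior_common == 1.0:
            final = mu_av
        else:
            d2 = _disparity_sq(a - v, params)
            log_odds = (
                logit(params.prior_common)
                + _effective_repetitions(stimulus) * params.lambda_sync
                - params.kappa_content * d2
            )
            pc = expit(log_odds)[:, None]
            final = pc * mu_av + (1.0 - pc) * a

    pmat = _prototype_matrix(params.prototypes)
    d2cat = ((final[:, None, :] - pmat[None, :, :]) ** 2).sum(axis=-1)
    idx = np.argmin(d2cat, axis=1)
    return np.bincount(idx, minlength=3)


def predict_percept_distribution(
    params: CIMSParams,
    stimulus: StimulusSpec,
    n_mc: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PerceptDistribution:
    """Monte Carlo percept probabilities for a stimulus.

    Runs encode -> integrate -> common-cause posterior -> model averaging
    -> classify for ``n_mc`` independent trials. Identical seeds and
    parameters reproduce bit-identical output.
    """
    if int(n_mc) != n_mc or n_mc < 1:
        raise ValueError("n_mc must be an integer >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = _simulate_category_counts(params, stimulus, int(n_mc), rng)
    p = counts / counts.sum()
    return PerceptDistribution(*p)


# ---------------------------------------------------------------------------
# analytic percept probabilities (constant common-cause weight)
# ---------------------------------------------------------------------------

def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    """P(U1 <= t1, U2 <= t2) for standard bivariate normal with correlation rho."""
    if rho > 1 - 1e-9:
        return float(norm.cdf(min(t1, t2)))
    if rho < -1 + 1e-9:
        return float(max(0.0, norm.cdf(t1) - norm.cdf(-t2)))
    return float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2])
    )


def _gaussian_cell_probability(
    label: str, mean: np.ndarray, cov: np.ndarray, prototypes: Mapping[str, np.ndarray]
) -> float:
    """Gaussian measure of a nearest-prototype (Voronoi) cell.

    With three prototypes each cell is the intersection of two half-planes
    a'x <= b, so the probability is a bivariate normal CDF after
    standardization.
    """
    protos = validate_prototypes(prototypes)
    pi = protos[label]
    halfplanes = []
    for other, pj in protos.items():
        if other == label:
            continue
        a = 2.0 * (pj - pi)
        b = float(pj @ pj - pi @ pi)
        halfplanes.append((a, b))
    (a1, b1), (a2, b2) = halfplanes
    s1 = math.sqrt(max(a1 @ cov @ a1, 1e-300))
    s2 = math.sqrt(max(a2 @ cov @ a2, 1e-300))
    t1 = (b1 - a1 @ mean) / s1
    t2 = (b2 - a2 @ mean) / s2
    rho = float(a1 @ cov @ a2) / (s1 * s2)
    return _bvn_cdf(t1, t2, max(-1.0, min(1.0, rho)))


def gaussian_percept_distribution(params: CIMSParams, stimulus: StimulusSpec) -> PerceptDistribution:
    """Closed-form percept probabilities when the common-cause weight is constant.

    Valid when ``kappa_content == 0``: the common-cause posterior then does
    not depend on the encoded disparity, so the final representation is a
    fixed linear map of the two Gaussian encodings and is itself Gaussian.
    Category probabilities are the Gaussian measures of the linear decision
    regions. Serves as the analytic counterpart of
    :func:`predict_percept_distribution`.
    """
    if params.kappa_content != 0.0:
        raise ValueError(
            "analytic percept probabilities require kappa_content == 0 "
            "(constant common-cause weight)"
        )
    mu_a = params.prototypes[stimulus.auditory_token]
    mu_v = params.prototypes[stimulus.visual_token]
    sig_a, sig_v = params.noise.sigma_A, params.noise.sigma_V

    if params.prior_common in (0.0, 1.0):
        pc = params.prior_common
    else:
        pc = float(
            expit(logit(params.prior_common) + _effective_repetitions(stimulus) * params.lambda_sync)
        )

    if pc == 0.0:
        mean, cov = mu_a, sig_a
    else:
        prec_a = _inv_pd(sig_a, "sigma_A")
        prec_v = _inv_pd(sig_v, "sigma_V")
        s = np.linalg.inv(prec_a + prec_v)
        l_a = pc * s @ prec_a + (1.0 - pc) * np.eye(2)
        l_v = pc * s @ prec_v
        mean = l_a @ mu_a + l_v @ mu_v
        cov = l_a @ sig_a @ l_a.T + l_v @ sig_v @ l_v.T
        cov = 0.5 * (cov + cov.T)

    probs = np.array(
        [_gaussian_cell_probability(c, mean, cov, params.prototypes) for c in CATEGORIES]
    )
    probs = np.clip(probs, 0.0, None)
    return PerceptDistribution(*(probs / probs.sum()))


# ---------------------------------------------------------------------------
# parameter file I/O (JSON)
# ---------------------------------------------------------------------------

def params_to_dict(params: CIMSParams, seed: int | None = None) -> dict:
    d = {
        "prototypes": {k: list(map(float, v)) for k, v in params.prototypes.items()},
        "sigma_A": params.noise.sigma_A.tolist(),
        "sigma_V": params.noise.sigma_V.tolist(),
        "prior_common": params.prior_common,
        "lambda_sync": params.lambda_sync,
        "kappa_content": params.kappa_content,
        "disparity_metric": params.disparity_metric,
    }
    if seed is not None:
        d["seed"] = int(seed)
    return d


def params_from_dict(d: Mapping) -> tuple[CIMSParams, int | None]:
    """Build parameters from a JSON-style dict; returns (params, seed)."""
    kwargs = {}
    if "prototypes" in d:
        kwargs["prototypes"] = d["prototypes"]
    noise_kwargs = {}
    if "sigma_A" in d:
        noise_kwargs["sigma_A"] = np.asarray(d["sigma_A"], dtype=float)
    if "sigma_V" in d:
        noise_kwargs["sigma_V"] = np.asarray(d["sigma_V"], dtype=float)
    if noise_kwargs:
        kwargs["noise"] = ModalityNoise(**noise_kwargs)
    for key in ("prior_common", "lambda_sync", "kappa_content", "disparity_metric"):
        if key in d:
            kwargs[key] = d[key]
    seed = d.get("seed")
    return CIMSParams(**kwargs), (int(seed) if seed is not None else None)


def save_params(params: CIMSParams, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params_to_dict(params, seed=seed), fh, indent=2)
        fh.write("\n")


def load_params(path) -> tuple[CIMSParams, int | None]:
    with open(path, encoding="utf-8") as fh:
        return params_from_dict(json.load(fh))
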