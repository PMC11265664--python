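"""Core statistical model: two-stratum nonlinear mixed-effects structure.

Each plant ``i`` carries an ``m``-vector of growth parameters ``phi_i``
driving its trajectory through a growth curve ``g``::

    y_ij  = g(phi_i, t_ij) + eps_ij,      eps_ij ~ N(0, sigma2)
    phi_i = X_i beta + Z_i u + p_i,       p_i ~ N(0, P)
    u ~ N(0, K (x) G)

``u`` stacks one ``q``-vector of genetic effects per variety (variety-major
layout); ``K`` is the variety-by-variety genetic relationship matrix and
``G`` the q-by-q genetic covariance, so ``K (x) G`` (Kronecker product)
correlates effects of related varieties.  ``Z_i`` is the variety-block
incidence matrix ``(0 ... Z_{v_i} ... 0)``: it is never materialized; all
algebra uses the per-plant block ``Z_{v_i}`` and the plant's variety index.

Kronecker quantities are computed through factorized identities
(``|K (x) G| = |K|^q |G|^{N_v}``, quadratic forms via the trace identity
``u' (K^-1 (x) G^-1) u = tr(G^-1 S(u))`` with
``S(u) = sum_{v,w} [K^-1]_{vw} u_v u_w'``); a dense Kronecker matrix is
formed only where it is unavoidable, namely the (q N_v)-dimensional
precision of ``u | phi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

from .growth_models import GrowthCurve, get_curve

__all__ = [
    "PlantRecord",
    "Dataset",
    "DesignSpec",
    "design_from_terms",
    "Theta",
    "Kinship",
    "LatentState",
    "DesignMatrices",
    "build_designs",
    "complete_log_likelihood",
    "u_conditional",
    "marginal_phi_covariance",
]


class SchemaError(ValueError):
    """Inconsistent or incomplete model inputs."""


class NumericalError(np.linalg.LinAlgError):
    """Linear-algebra failure (singular or indefinite matrix)."""


# ---------------------------------------------------------------------------
# linear-algebra helpers


def symmetrize(mat: np.ndarray) -> np.ndarray:
    return 0.5 * (mat + mat.T)


def chol_lower(mat: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Cholesky factor with one jitter retry (1e-8 * trace/dim on the diagonal)."""
    mat = symmetrize(np.asarray(mat, dtype=float))
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(mat) / mat.shape[0]
        if jitter <= 0:
            jitter = 1e-12
        try:
            return np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            raise NumericalError(
                f"{what} is not positive definite even after jitter {jitter:.2e}; "
                "consider adding a larger diagonal jitter"
            ) from None


def spd_inverse(mat: np.ndarray, what: str = "matrix") -> np.ndarray:
    low = chol_lower(mat, what)
    inv = linalg.cho_solve((low, True), np.eye(mat.shape[0]))
    return symmetrize(inv)


def spd_logdet(mat: np.ndarray, what: str = "matrix") -> float:
    low = chol_lower(mat, what)
    return 2.0 * float(np.sum(np.log(np.diag(low))))


# ---------------------------------------------------------------------------
# containers


@dataclass
class PlantRecord:
    """One plant's longitudinal record."""

    plant_id: str
    variety: str
    covariates: Dict[str, float]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise SchemaError(
                f"plant {self.plant_id}: times and values differ in length"
            )
        if self.times.size < 1:
            raise SchemaError(f"plant {self.plant_id}: no observations")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(f"plant {self.plant_id}: non-finite values")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.values = self.values[order]

    @property
    def n_obs(self) -> int:
        return self.times.size


@dataclass
class Dataset:
    """Plants with observation vectors, grouped into varieties.

    ``variety_index`` maps variety label to a 0-based index; the ordering
    fixes the layout of ``u`` and the rows/columns of the kinship matrix.
    """

    plants: List[PlantRecord]
    variety_index: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.variety_index:
            # order of first appearance
            idx: Dict[str, int] = {}
            for rec in self.plants:
                idx.setdefault(rec.variety, len(idx))
            self.variety_index = idx
        for rec in self.plants:
            if rec.variety not in self.variety_index:
                raise SchemaError(f"variety '{rec.variety}' missing from index")

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_varieties(self) -> int:
        return len(self.variety_index)

    @property
    def varieties(self) -> List[str]:
        return sorted(self.variety_index, key=self.variety_index.get)

    @property
    def total_obs(self) -> int:
        return sum(rec.n_obs for rec in self.plants)

    def subset(self, keep) -> "Dataset":
        """Dataset restricted to the given plant indices, variety index kept."""
        plants = [self.plants[i] for i in keep]
        return Dataset(plants, dict(self.variety_index))


@dataclass
class DesignSpec:
    """Curve choice plus per-plant incidence-matrix builder.

    ``builder(record) -> (X_i, Z_block)`` where ``X_i`` is m-by-p and
    ``Z_block`` is the m-by-q block occupying the plant's variety slot of
    the full incidence matrix ``Z_i``.
    """

    curve: str
    p: int
    q: int
    builder: Callable[[PlantRecord], Tuple[np.ndarray, np.ndarray]]
    constants: Dict[str, float] = field(default_factory=dict)
    fixed_names: Optional[List[str]] = None
    genetic_names: Optional[List[str]] = None

    def get_curve(self) -> GrowthCurve:
        return get_curve(self.curve, **self.constants)


def design_from_terms(
    curve: str,
    fixed_terms: Sequence[str],
    genetic_terms: Sequence[str],
    constants: Optional[Dict[str, float]] = None,
) -> DesignSpec:
    """Declarative design: each term is ``"1"`` (intercept) or a covariate name.

    A term contributes one scaled identity block ``value * I_m`` to the
    design, so ``p = m * len(fixed_terms)`` and ``q = m * len(genetic_terms)``
    with beta laid out term-major (all intercepts first, then each
    covariate's effects, one per growth parameter).  For the logistic model
    with irrigation this reproduces ``X_i = (I_2 | x_i I_2)``.
    """
    constants = dict(constants or {})
    m = get_curve(curve).m

    def builder(record: PlantRecord):
        def block(terms):
            cols = []
            for term in terms:
                if term == "1":
                    value = 1.0
                else:
                    if term not in record.covariates:
                        raise SchemaError(
                            f"plant {record.plant_id}: covariate '{term}' missing"
                        )
                    value = float(record.covariates[term])
                cols.append(value * np.eye(m))
            return np.hstack(cols) if cols else np.zeros((m, 0))

        return block(fixed_terms), block(genetic_terms)

    trait = [f"phi{j + 1}" for j in range(m)]
    fixed_names = [f"{t}:{tr}" for t in fixed_terms for tr in trait]
    genetic_names = [f"{t}:{tr}" for t in genetic_terms for tr in trait]
    return DesignSpec(
        curve=curve,
        p=m * len(fixed_terms),
        q=m * len(genetic_terms),
        builder=builder,
        constants=constants,
        fixed_names=fixed_names,
        genetic_names=genetic_names,
    )


@dataclass
class Theta:
    """Full model parameter: fixed effects and the three variance components."""

    beta: np.ndarray
    sigma2: float
    P: np.ndarray
    G: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.P = symmetrize(np.atleast_2d(np.asarray(self.P, dtype=float)))
        self.G = symmetrize(np.atleast_2d(np.asarray(self.G, dtype=float)))
        self.sigma2 = float(self.sigma2)
        if self.sigma2 <= 0:
            raise SchemaError("sigma2 must be positive")

    def copy(self) -> "Theta":
        return Theta(self.beta.copy(), self.sigma2, self.P.copy(), self.G.copy())

    def is_finite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.beta))
            and np.isfinite(self.sigma2)
            and np.all(np.isfinite(self.P))
            and np.all(np.isfinite(self.G))
        )


@dataclass
class Kinship:
    """Genetic relationship matrix over varieties, in dataset variety order."""

    K: np.ndarray
    varieties: List[str]

    def __post_init__(self):
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        n = self.K.shape[0]
        if self.K.shape != (n, n) or n != len(self.varieties):
            raise SchemaError("kinship matrix shape does not match variety list")
        if np.max(np.abs(self.K - self.K.T)) > 1e-10:
            raise SchemaError("kinship matrix is not symmetric (tolerance 1e-10)")
        eig = np.linalg.eigvalsh(symmetrize(self.K))
        if eig[0] < -1e-8 * max(eig[-1], 1.0):
            raise SchemaError("kinship matrix has substantially negative eigenvalues")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def aligned_to(self, dataset: Dataset) -> "Kinship":
        """Check order against a dataset; raise on mismatch (never reorder silently)."""
        if self.varieties != dataset.varieties:
            raise SchemaError(
                "kinship variety order does not match the dataset; "
                "reorder the kinship input explicitly"
            )
        return self


@dataclass
class LatentState:
    """Current draws of the latent variables plus SA accumulators."""

    phi: np.ndarray  # (N_p, m)
    u: np.ndarray  # (q * N_v,) variety-major
    sa_stats: Optional[object] = None

    def u_matrix(self, q: int) -> np.ndarray:
        """Reshape ``u`` to (N_v, q): row v is variety v's effect vector."""
        return self.u.reshape(-1, q)


# ---------------------------------------------------------------------------
# stacked design workspace


@dataclass
class DesignMatrices:
    """Per-plant incidence matrices stacked for vectorized computation.

    Plants are grouped into covariate patterns: plants sharing an identical
    ``X_i`` (and hence ``Z_block``) form one pattern ``c`` with shared design
    ``X_c``; sufficient statistics are aggregated per pattern.
    """

    X: np.ndarray  # (N_p, m, p)
    Zb: np.ndarray  # (N_p, m, q)
    v_idx: np.ndarray  # (N_p,)
    times: np.ndarray  # (N_p, n_max) padded
    values: np.ndarray  # (N_p, n_max) padded
    mask: np.ndarray  # (N_p, n_max) bool
    n_obs: np.ndarray  # (N_p,)
    pattern_of: np.ndarray  # (N_p,) pattern index per plant
    pattern_X: List[np.ndarray]  # shared X_c per pattern
    pattern_counts: np.ndarray  # plants per pattern

    @property
    def n_plants(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[2]

    @property
    def q(self) -> int:
        return self.Zb.shape[2]

    @property
    def total_obs(self) -> int:
        return int(self.n_obs.sum())

    def phi_mean(self, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
        """E[phi_i | u] = X_i beta + Z_block u_{v_i}, stacked (N_p, m)."""
        u_mat = u.reshape(-1, self.q)
        return self.X @ beta + np.einsum(
            "imq,iq->im", self.Zb, u_mat[self.v_idx], optimize=True
        )


def build_designs(dataset: Dataset, spec: DesignSpec) -> DesignMatrices:
    """Build and stack per-plant incidence matrices.

    The full ``Z_i`` is represented sparsely by ``(v_idx, Z_block)``;
    ``Z_i u`` is always computed as ``Z_block u_{v_i}``.
    """
    curve = spec.get_curve()
    m = curve.m
    n_p = dataset.n_plants
    if n_p == 0:
        raise SchemaError("empty dataset")
    x_list, zb_list = [], []
    for rec in dataset.plants:
        x_i, zb_i = spec.builder(rec)
        x_i = np.atleast_2d(np.asarray(x_i, dtype=float))
        zb_i = np.atleast_2d(np.asarray(zb_i, dtype=float))
        if x_i.shape != (m, spec.p):
            raise SchemaError(
                f"plant {rec.plant_id}: X_i shape {x_i.shape}, expected {(m, spec.p)}"
            )
        if zb_i.shape != (m, spec.q):
            raise SchemaError(
                f"plant {rec.plant_id}: Z_block shape {zb_i.shape}, "
                f"expected {(m, spec.q)}"
            )
        x_list.append(x_i)
        zb_list.append(zb_i)
    X = np.stack(x_list)
    Zb = np.stack(zb_list)
    v_idx = np.array([dataset.variety_index[rec.variety] for rec in dataset.plants])

    n_obs = np.array([rec.n_obs for rec in dataset.plants])
    n_max = int(n_obs.max())
    times = np.zeros((n_p, n_max))
    values = np.zeros((n_p, n_max))
    mask = np.zeros((n_p, n_max), dtype=bool)
    for i, rec in enumerate(dataset.plants):
        times[i, : rec.n_obs] = rec.times
        values[i, : rec.n_obs] = rec.values
        mask[i, : rec.n_obs] = True

    keys: Dict[bytes, int] = {}
    pattern_of = np.empty(n_p, dtype=int)
    pattern_X: List[np.ndarray] = []
    for i in range(n_p):
        key = X[i].tobytes() + Zb[i].tobytes()
        if key not in keys:
            keys[key] = len(pattern_X)
            pattern_X.append(X[i])
        pattern_of[i] = keys[key]
    pattern_counts = np.bincount(pattern_of, minlength=len(pattern_X))

    return DesignMatrices(
        X=X,
        Zb=Zb,
        v_idx=v_idx,
        times=times,
        values=values,
        mask=mask,
        n_obs=n_obs,
        pattern_of=pattern_of,
        pattern_X=pattern_X,
        pattern_counts=pattern_counts,
    )


# ---------------------------------------------------------------------------
# densities and conditionals


def genetic_scatter(u_mat: np.ndarray, k_inv: np.ndarray) -> np.ndarray:
    """S(u) = sum_{v,w} [K^-1]_{vw} u_v u_w' = U' K^-1 U, a q-by-q matrix."""
    return symmetrize(u_mat.T @ k_inv @ u_mat)


def residual_ss(
    designs: DesignMatrices, curve: GrowthCurve, phi: np.ndarray
) -> np.ndarray:
    """Per-plant sum of squared residuals y_ij - g(phi_i, t_ij)."""
    fitted = curve.evaluate(phi, designs.times)
    resid = np.where(designs.mask, designs.values - fitted, 0.0)
    return np.einsum("ij,ij->i", resid, resid)


def complete_log_likelihood(
    dataset: Dataset,
    spec: DesignSpec,
    theta: Theta,
    kinship: Kinship,
    latent: LatentState,
    designs: Optional[DesignMatrices] = None,
) -> float:
    """log p(y | phi; sigma2) + log p(phi | u; beta, P) + log p(u; G, K).

    All three terms are Gaussian log-densities.  The genetic term never
    forms the (q N_v)-square Kronecker matrix: its log-determinant uses
    ``|K (x) G| = |K|^q |G|^{N_v}`` and its quadratic form the identity
    ``u'(K^-1 (x) G^-1)u = tr(G^-1 S(u))``.
    """
    if designs is None:
        designs = build_designs(dataset, spec)
    curve = spec.get_curve()
    n_total = designs.total_obs
    n_v, q = kinship.n, designs.q
    log2pi = np.log(2.0 * np.pi)

    rss = float(residual_ss(designs, curve, latent.phi).sum())
    ll_y = -0.5 * (n_total * (log2pi + np.log(theta.sigma2)) + rss / theta.sigma2)

    resid_phi = latent.phi - designs.phi_mean(theta.beta, latent.u)
    p_inv = spd_inverse(theta.P, "P")
    quad_phi = float(np.einsum("im,mn,in->", resid_phi, p_inv, resid_phi))
    ll_phi = -0.5 * (
        designs.n_plants * (designs.m * log2pi + spd_logdet(theta.P, "P")) + quad_phi
    )

    k_inv = spd_inverse(kinship.K, "K")
    g_inv = spd_inverse(theta.G, "G")
    scatter = genetic_scatter(latent.u_matrix(q), k_inv)
    ll_u = -0.5 * (
        q * n_v * log2pi
        + q * spd_logdet(kinship.K, "K")
        + n_v * spd_logdet(theta.G, "G")
        + float(np.trace(g_inv @ scatter))
    )
    return ll_y + ll_phi + ll_u


def u_conditional(
    theta: Theta,
    kinship: Kinship,
    designs: DesignMatrices,
    phi: np.ndarray,
    return_chol: bool = False,
):
    """Exact Gaussian conditional of ``u`` given ``phi`` (and theta).

    Given phi, the model is linear-Gaussian in u:
    ``phi_i - X_i beta = Z_i u + p_i``, so

        precision = sum_i Z_i' P^-1 Z_i + K^-1 (x) G^-1
        mean      = precision^-1 sum_i Z_i' P^-1 (phi_i - X_i beta)

    The data term is block-diagonal over varieties and is assembled from the
    per-plant blocks.  Returns ``(mean, cov)``, or ``(mean, chol_precision)``
    when ``return_chol`` (used for exact sampling).
    """
    q, n_v = designs.q, kinship.n
    p_inv = spd_inverse(theta.P, "P")
    k_inv = spd_inverse(kinship.K, "K")
    g_inv = spd_inverse(theta.G, "G")

    # per-plant data-precision blocks Z_b' P^-1 Z_b, scattered by variety
    blocks = np.einsum("imq,mn,inr->iqr", designs.Zb, p_inv, designs.Zb, optimize=True)
    data_prec = np.zeros((n_v, q, q))
    np.add.at(data_prec, designs.v_idx, blocks)

    resid = phi - designs.X @ theta.beta
    rhs_terms = np.einsum("imq,mn,in->iq", designs.Zb, p_inv, resid, optimize=True)
    rhs = np.zeros((n_v, q))
    np.add.at(rhs, designs.v_idx, rhs_terms)

    precision = np.kron(k_inv, g_inv)
    for v in range(n_v):
        sl = slice(v * q, (v + 1) * q)
        precision[sl, sl] += data_prec[v]
    precision = symmetrize(precision)

    low = chol_lower(precision, "u | phi precision")
    mean = linalg.cho_solve((low, True), rhs.ravel())
    if return_chol:
        return mean, low
    cov = linalg.cho_solve((low, True), np.eye(q * n_v))
    return mean, symmetrize(cov)


def marginal_phi_covariance(
    spec: DesignSpec,
    theta: Theta,
    kinship: Kinship,
    designs: DesignMatrices,
    plant: int,
) -> np.ndarray:
    """Marginal covariance of phi_i: Z_i (K (x) G) Z_i' + P.

    Because ``Z_i`` touches only the plant's own variety block, the genetic
    part reduces to ``K_{v_i v_i} Z_block G Z_block'``.
    """
    if not 0 <= plant < designs.n_plants:
        raise SchemaError(f"plant index {plant} out of range")
    zb = designs.Zb[plant]
    k_vv = kinship.K[designs.v_idx[plant], designs.v_idx[plant]]
    return symmetrize(k_vv * (zb @ theta.G @ zb.T) + theta.P)
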