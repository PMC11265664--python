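"""Scenario simulator: synthetic phenotypes, kinship and ground truth.

Three presets mirror the numerical study designs:

* ``scenario1`` -- logistic curve, 2000 plants from 50 (or 100) varieties,
  one observation per unit time step on [1, 45];
* ``scenario2`` -- logistic curve, 800 plants from 200 varieties, either a
  rich (45-point) or sparse (10-point) regular sampling of [1, 45];
* ``prediction`` -- logistic curve with a quantitative environment
  covariate ``x`` in {1, 2, 3} acting on both growth parameters
  (phi_i1 = mu_A + x_i delta_A + u_{v,A} + p_i1, likewise phi_i2), 225
  varieties with six plants each (two per environment), and G = k P for
  k in {1, 2}, i.e. generating heritabilities k/(k+1) on every trait.

Every preset field is overridable, so the same designs run at reduced
size on a desk.  Kinship is simulated from Hardy-Weinberg marker genotypes
and the additive genomic relationship matrix, preserving GRM-like spectra
rather than drawing an arbitrary positive-definite matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_interface import compute_grm
from .model_core import (
    Dataset,
    DesignSpec,
    Kinship,
    PlantRecord,
    Theta,
    chol_lower,
    design_from_terms,
)

__all__ = [
    "ScenarioPreset",
    "SimulationResult",
    "simulate_kinship",
    "simulate_dataset",
    "preset_catalog",
    "get_preset",
]


@dataclass
class ScenarioPreset:
    """Complete recipe for one synthetic experiment."""

    name: str
    curve: str
    constants: Dict[str, float]
    fixed_terms: List[str]
    genetic_terms: List[str]
    theta: Theta
    n_plants: int
    n_varieties: int
    n_obs: int
    time_interval: Tuple[float, float] = (1.0, 45.0)
    env_covariate: Optional[str] = None
    env_levels: Optional[List[float]] = None
    plants_per_env: int = 2
    n_markers: int = 2000
    maf_range: Tuple[float, float] = (0.05, 0.5)

    def design_spec(self) -> DesignSpec:
        return design_from_terms(
            self.curve, self.fixed_terms, self.genetic_terms, self.constants
        )

    def with_overrides(self, **overrides) -> "ScenarioPreset":
        return replace(self, **overrides)


@dataclass
class SimulationResult:
    """Synthetic dataset together with its generating ground truth."""

    dataset: Dataset
    kinship: Kinship
    genotypes: np.ndarray
    spec: DesignSpec
    preset: ScenarioPreset
    u: np.ndarray  # (q N_v,) variety-major
    p: np.ndarray  # (N_p, m)
    phi: np.ndarray  # (N_p, m)


def simulate_kinship(
    n_varieties: int,
    n_markers: int = 2000,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    varieties: Optional[List[str]] = None,
) -> Tuple[Kinship, np.ndarray]:
    """Marker-based kinship for unrelated varieties.

    Per-marker allele frequencies are uniform on ``maf_range``; genotypes
    (coded -1/0/1) follow Hardy-Weinberg proportions independently per
    variety.  The additive genomic relationship matrix is computed from the
    genotypes, rescaled to unit mean diagonal, and stabilized with a 1e-6
    diagonal jitter.
    """
    if n_markers < 1:
        raise ValueError("need at least one marker")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(lo, hi, size=n_markers)
    us = rng.random((n_varieties, n_markers))
    hom_ref = (1.0 - freq) ** 2
    het = 2.0 * freq * (1.0 - freq)
    geno = np.where(us < hom_ref, -1, np.where(us < hom_ref + het, 0, 1)).astype(
        np.int8
    )
    if varieties is None:
        varieties = [f"v{j + 1:03d}" for j in range(n_varieties)]
    if n_varieties == 1:
        return Kinship(np.array([[1.0]]), varieties), geno
    k_mat = compute_grm(geno, rescale=True)
    k_mat = k_mat + 1e-6 * np.eye(n_varieties)
    return Kinship(k_mat, varieties), geno


def _allocate_plants(preset: ScenarioPreset) -> List[Tuple[int, Dict[str, float]]]:
    """(variety index, covariates) per plant."""
    if preset.env_covariate is not None:
        plants = []
        for v in range(preset.n_varieties):
            for level in preset.env_levels:
                for _ in range(preset.plants_per_env):
                    plants.append((v, {preset.env_covariate: float(level)}))
        return plants
    base, extra = divmod(preset.n_plants, preset.n_varieties)
    plants = []
    for v in range(preset.n_varieties):
        count = base + (1 if v < extra else 0)
        plants.extend((v, {}) for _ in range(count))
    return plants


def simulate_dataset(
    preset: ScenarioPreset,
    seed: int = 0,
    kinship: Optional[Kinship] = None,
) -> SimulationResult:
    """Draw one dataset under the preset's generating model.

    ``u ~ N(0, K (x) G)`` is drawn through the Cholesky factors of K and G
    (``U = L_K Z L_G'`` has exactly the Kronecker covariance in
    variety-major layout); plant effects and residuals are i.i.d. Gaussian.
    """
    rng = np.random.default_rng(seed)
    spec = preset.design_spec()
    theta = preset.theta
    m = spec.get_curve().m
    q = spec.q

    if kinship is None:
        kin_seed = int(rng.integers(2**31))
        kinship, geno = simulate_kinship(
            preset.n_varieties, preset.n_markers, preset.maf_range, kin_seed
        )
    else:
        geno = np.zeros((kinship.n, 0), dtype=np.int8)

    l_k = chol_lower(kinship.K, "K")
    l_g = chol_lower(theta.G, "G")
    u_mat = l_k @ rng.standard_normal((kinship.n, q)) @ l_g.T
    u = u_mat.ravel()

    allocation = _allocate_plants(preset)
    times = np.linspace(*preset.time_interval, preset.n_obs)
    l_p = chol_lower(theta.P, "P")
    curve = spec.get_curve()

    plants: List[PlantRecord] = []
    p_effects = np.empty((len(allocation), m))
    phi_all = np.empty((len(allocation), m))
    variety_labels = kinship.varieties
    for i, (v, covs) in enumerate(allocation):
        rec = PlantRecord(
            plant_id=f"p{i + 1:04d}",
            variety=variety_labels[v],
            covariates=covs,
            times=times,
            values=np.zeros_like(times),
        )
        x_i, zb_i = spec.builder(rec)
        p_i = l_p @ rng.standard_normal(m)
        phi_i = x_i @ theta.beta + zb_i @ u_mat[v] + p_i
        noise = np.sqrt(theta.sigma2) * rng.standard_normal(times.size)
        rec.values = curve.evaluate(phi_i, times) + noise
        p_effects[i] = p_i
        phi_all[i] = phi_i
        plants.append(rec)

    vmap = {label: j for j, label in enumerate(variety_labels)}
    dataset = Dataset(plants, vmap)
    return SimulationResult(
        dataset=dataset,
        kinship=kinship,
        genotypes=geno,
        spec=spec,
        preset=preset,
        u=u,
        p=p_effects,
        phi=phi_all,
    )


# ---------------------------------------------------------------------------
# preset catalog


def _scenario_theta() -> Theta:
    return Theta(
        beta=np.array([50.0, 13.0]),
        sigma2=4.0,
        P=np.diag([6.0, 0.4]),
        G=np.diag([25.0, 1.5]),
    )


def _prediction_theta(k: int) -> Theta:
    p_mat = np.diag([3.0, 0.1])
    return Theta(
        beta=np.array([50.0, 25.0, 0.0, 25.0]),  # mu_A, mu_B, delta_A, delta_B
        sigma2=8.0,
        P=p_mat,
        G=float(k) * p_mat,
    )


def preset_catalog() -> Dict[str, str]:
    """Names and one-line descriptions of the shipped presets."""
    return {
        "scenario1": "2000 plants, 50 varieties, 45 unit-spaced observations",
        "scenario1_100v": "scenario1 with 100 varieties",
        "scenario2": "800 plants, 200 varieties, sparse 10-point sampling",
        "scenario2_rich": "scenario2 with the rich 45-point sampling",
        "prediction": "225 varieties x 6 plants, env x in {1,2,3}, G = k P (k=1)",
        "prediction_k2": "prediction design with k=2 (heritability 2/3)",
    }


def get_preset(name: str, k: Optional[int] = None, **overrides) -> ScenarioPreset:
    """Fetch a preset by name; every field can be overridden.

    ``k`` rebuilds the prediction design's G = k P.  Note delta_A defaults
    to zero: the prediction design specifies no average irrigation effect
    on the asymptote (override ``theta`` to change it).
    """
    base: ScenarioPreset
    if name in {"scenario1", "scenario1_100v"}:
        base = ScenarioPreset(
            name=name,
            curve="logistic",
            constants={"gamma": 0.3},
            fixed_terms=["1"],
            genetic_terms=["1"],
            theta=_scenario_theta(),
            n_plants=2000,
            n_varieties=50 if name == "scenario1" else 100,
            n_obs=45,
        )
    elif name in {"scenario2", "scenario2_rich"}:
        base = ScenarioPreset(
            name=name,
            curve="logistic",
            constants={"gamma": 0.3},
            fixed_terms=["1"],
            genetic_terms=["1"],
            theta=_scenario_theta(),
            n_plants=800,
            n_varieties=200,
            n_obs=10 if name == "scenario2" else 45,
        )
    elif name in {"prediction", "prediction_k2"}:
        kk = k if k is not None else (2 if name == "prediction_k2" else 1)
        n_varieties = int(overrides.pop("n_varieties", 225))
        plants_per_env = int(overrides.pop("plants_per_env", 2))
        base = ScenarioPreset(
            name=name,
            curve="logistic",
            constants={"gamma": 0.3},
            fixed_terms=["1", "x"],
            genetic_terms=["1"],
            theta=_prediction_theta(kk),
            n_plants=n_varieties * 3 * plants_per_env,
            n_varieties=n_varieties,
            n_obs=10,
            # half-times mu_B + x delta_B reach 100; the window must cover
            # the curves or the asymptote is unidentifiable
            time_interval=(1.0, 150.0),
            env_covariate="x",
            env_levels=[1.0, 2.0, 3.0],
            plants_per_env=plants_per_env,
        )
    else:
        raise KeyError(
            f"unknown preset '{name}'; available: {sorted(preset_catalog())}"
        )
    if k is not None and name.startswith("scenario"):
        raise ValueError("k only applies to the prediction presets")
    if overrides:
        base = base.with_overrides(**overrides)
    return base
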