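"""Growth prediction and cv0/cv1/cv2 cross-validation.

Predictions plug the estimated fixed effects and genetic effects into the
model mean: ``phi_hat_i = X_i beta_hat + Z_i u_hat`` and
``y_hat_i(t) = g(phi_hat_i, t)`` (plant effects ``p_i`` enter at their prior
mean of zero).  Three cross-validation schemes probe different prediction
tasks:

* cv0 -- known varieties in an unseen environment: leave one level of the
  environment covariate out (round-robin over levels);
* cv1 -- unseen varieties: hold entire varieties out and deduce their
  genetic effects from the kinship matrix through the Gaussian conditional
  expectation;
* cv2 -- unseen variety-by-environment combinations: every variety and
  every environment remain in training, so estimated effects are used
  directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import (
    Dataset,
    DesignSpec,
    Kinship,
    SchemaError,
    Theta,
    build_designs,
)
from .map_predict import map_settings, map_u
from .saem_fit import SAEMSettings, fit

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "predict_phi",
    "predict_trajectory",
    "extend_u",
    "relative_difference",
    "run_cv",
]


def predict_phi(
    dataset: Dataset,
    spec: DesignSpec,
    theta: Theta,
    u_hat: np.ndarray,
    u_varieties: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """phi_hat_i = X_i beta_hat + Z_i u_hat for every plant, stacked (N_p, m).

    ``u_hat`` is variety-major over ``u_varieties`` (defaults to the
    dataset's variety order).  A plant whose variety has no entry raises;
    use :func:`extend_u` first for varieties outside the fitted set.
    """
    designs = build_designs(dataset, spec)
    q = designs.q
    u_mat = np.asarray(u_hat, dtype=float).reshape(-1, q)
    if u_varieties is None:
        u_varieties = dataset.varieties
    index = {v: j for j, v in enumerate(u_varieties)}
    rows = np.empty(dataset.n_plants, dtype=int)
    for i, rec in enumerate(dataset.plants):
        if rec.variety not in index:
            raise SchemaError(
                f"variety '{rec.variety}' has no estimated genetic effect; "
                "extend u via the kinship matrix first"
            )
        rows[i] = index[rec.variety]
    return designs.X @ theta.beta + np.einsum(
        "imq,iq->im", designs.Zb, u_mat[rows], optimize=True
    )


def predict_trajectory(spec: DesignSpec, phi_hat: np.ndarray, times) -> np.ndarray:
    """y_hat(t) = g(phi_hat, t), elementwise over times."""
    return spec.get_curve().evaluate(phi_hat, times)


def extend_u(
    kinship_full: Kinship,
    observed_varieties: Sequence[str],
    u_obs: np.ndarray,
    q: int,
) -> Tuple[List[str], np.ndarray]:
    """Genetic effects of unobserved varieties by Gaussian conditioning.

    Under ``u ~ N(0, K (x) G)`` the conditional expectation of the new
    block given the observed block is

        u_new = (K_no K_oo^-1 (x) I_q) u_obs

    (G cancels in the mean).  Returns the new variety labels, in
    ``kinship_full`` order, and their effect matrix of shape (n_new, q).
    """
    observed = list(observed_varieties)
    obs_set = set(observed)
    pos = {v: i for i, v in enumerate(kinship_full.varieties)}
    missing = obs_set - set(pos)
    if missing:
        raise SchemaError(f"observed varieties absent from kinship: {sorted(missing)}")
    new = [v for v in kinship_full.varieties if v not in obs_set]
    obs_ix = np.array([pos[v] for v in observed])
    new_ix = np.array([pos[v] for v in new], dtype=int)
    k_oo = kinship_full.K[np.ix_(obs_ix, obs_ix)]
    k_no = kinship_full.K[np.ix_(new_ix, obs_ix)]
    try:
        weights = np.linalg.solve(k_oo, k_no.T).T
    except np.linalg.LinAlgError:
        jitter = 1e-8 * max(np.trace(k_oo) / max(len(obs_ix), 1), 1.0)
        try:
            weights = np.linalg.solve(k_oo + jitter * np.eye(len(obs_ix)), k_no.T).T
        except np.linalg.LinAlgError:
            raise SchemaError(
                "observed kinship block is singular; add jitter to the kinship matrix"
            ) from None
    u_mat = np.asarray(u_obs, dtype=float).reshape(len(observed), q)
    return new, weights @ u_mat


def relative_difference(predicted, reference) -> np.ndarray:
    """Signed elementwise (predicted - reference) / reference.

    Zero reference entries are masked to NaN with a warning; an all-zero
    reference is an error.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    zero = reference == 0
    if np.all(zero):
        raise ValueError("reference values are all zero")
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero reference values masked to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (predicted - reference) / reference
    return np.where(zero, np.nan, out)


# ---------------------------------------------------------------------------
# cross-validation plans


@dataclass
class CVPlan:
    """Fold assignments for one CV scenario.

    ``assignments[rep][fold]`` is the set of validation units for that
    fold: environment values (cv0), variety labels (cv1) or
    ``(variety, environment)`` pairs (cv2).  Folds partition the scenario's
    unit set within each repetition.  ``folds_to_run`` restricts evaluation
    to the first so-many folds per repetition (e.g. a single 90/10 split
    with ``folds=10, folds_to_run=1``) while keeping the training fraction.
    """

    scenario: str
    folds: int
    repetitions: int
    seed: int
    env_covariate: Optional[str]
    assignments: List[List[set]] = field(default_factory=list)
    folds_to_run: Optional[int] = None

    def run_folds(self) -> int:
        return self.folds if self.folds_to_run is None else min(
            self.folds_to_run, self.folds
        )


def _partition(items: List, folds: int, rng: np.random.Generator) -> List[set]:
    items = list(items)
    order = rng.permutation(len(items))
    groups: List[set] = [set() for _ in range(folds)]
    for slot, ix in enumerate(order):
        groups[slot % folds].add(items[ix])
    return groups


def make_cv_plan(
    dataset: Dataset,
    scenario: str,
    folds: int = 5,
    repetitions: int = 1,
    seed: int = 0,
    env_covariate: Optional[str] = None,
    folds_to_run: Optional[int] = None,
) -> CVPlan:
    """Build fold assignments for cv0, cv1 or cv2.

    cv0 needs an environment covariate with at least three distinct levels:
    leaving one level of a two-level (e.g. binary) covariate out leaves a
    single level in training, confounding the covariate effect with the
    intercept -- the scheme is then infeasible, and this is reported as an
    error rather than silently producing a degenerate fit.
    """
    if scenario not in {"cv0", "cv1", "cv2"}:
        raise ValueError("scenario must be one of cv0, cv1, cv2")
    rng = np.random.default_rng(seed)
    if scenario in {"cv0", "cv2"} and env_covariate is None:
        raise SchemaError(f"{scenario} requires an environment covariate name")

    assignments: List[List[set]] = []
    if scenario == "cv0":
        levels = sorted({rec.covariates[env_covariate] for rec in dataset.plants})
        if len(levels) < 3:
            raise SchemaError(
                "cv0 is infeasible: the environment covariate "
                f"'{env_covariate}' has {len(levels)} level(s); at least "
                "three are needed to leave one out and still estimate its effect"
            )
        folds = len(levels)
        for _ in range(repetitions):
            assignments.append([{level} for level in levels])
    elif scenario == "cv1":
        varieties = dataset.varieties
        if folds > len(varieties):
            raise SchemaError("more folds than varieties")
        for _ in range(repetitions):
            assignments.append(_partition(varieties, folds, rng))
    else:  # cv2
        combos = sorted(
            {(rec.variety, rec.covariates[env_covariate]) for rec in dataset.plants}
        )
        per_variety: Dict[str, int] = {}
        for v, _ in combos:
            per_variety[v] = per_variety.get(v, 0) + 1
        for _ in range(repetitions):
            for attempt in range(100):
                groups = _partition(combos, folds, rng)
                bad = any(
                    sum(1 for c in grp if c[0] == v) == per_variety[v]
                    for grp in groups
                    for v in {c[0] for c in grp}
                )
                if not bad:
                    break
                if attempt == 0:
                    warnings.warn(
                        "cv2 fold left a variety with no training data; "
                        "re-randomizing",
                        RuntimeWarning,
                        stacklevel=2,
                    )
            else:
                raise SchemaError(
                    "could not build cv2 folds keeping every variety in training"
                )
            assignments.append(groups)
    return CVPlan(
        scenario=scenario,
        folds=folds,
        repetitions=repetitions,
        seed=seed,
        env_covariate=env_covariate,
        assignments=assignments,
        folds_to_run=folds_to_run,
    )


# ---------------------------------------------------------------------------
# harness


def _validation_mask(dataset: Dataset, plan: CVPlan, units: set) -> np.ndarray:
    mask = np.zeros(dataset.n_plants, dtype=bool)
    for i, rec in enumerate(dataset.plants):
        if plan.scenario == "cv0":
            mask[i] = rec.covariates[plan.env_covariate] in units
        elif plan.scenario == "cv1":
            mask[i] = rec.variety in units
        else:
            mask[i] = (rec.variety, rec.covariates[plan.env_covariate]) in units
    return mask


def _fold_seed(base: int, rep: int, fold: int) -> int:
    return int(np.random.SeedSequence([base, rep, fold]).generate_state(1)[0] % 2**31)


def run_cv(
    dataset: Dataset,
    spec: DesignSpec,
    kinship: Kinship,
    plan: CVPlan,
    settings: SAEMSettings,
    map_iter: Optional[SAEMSettings] = None,
    truth_phi: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Fit on each training fold and score validation predictions.

    Returns a long table with one row per validation relative difference:
    observation-scale rows (``kind='y'``, predicted trajectory vs the held
    out measurement at each observed time) and, when ``truth_phi`` is given
    (simulated data), parameter-scale rows (``kind='phi'``, predicted vs
    generating growth parameters).  Deterministic given ``plan.seed`` and
    ``settings``.
    """
    kinship.aligned_to(dataset)
    curve = spec.get_curve()
    rows = []
    for rep in range(plan.repetitions):
        for fold in range(plan.run_folds()):
            units = plan.assignments[rep][fold]
            val_mask = _validation_mask(dataset, plan, units)
            if not val_mask.any() or val_mask.all():
                raise SchemaError("degenerate fold: empty training or validation set")
            train_ix = np.flatnonzero(~val_mask)
            val_ix = np.flatnonzero(val_mask)

            if plan.scenario == "cv1":
                train_vars = [
                    v for v in dataset.varieties
                    if any(dataset.plants[i].variety == v for i in train_ix)
                ]
                vmap = {v: j for j, v in enumerate(train_vars)}
                train_ds = Dataset(
                    [dataset.plants[i] for i in train_ix], dict(vmap)
                )
                ix = np.array([dataset.variety_index[v] for v in train_vars])
                train_kin = Kinship(kinship.K[np.ix_(ix, ix)], train_vars)
            else:
                train_ds = dataset.subset(train_ix)
                train_vars = dataset.varieties
                train_kin = kinship

            seed = _fold_seed(plan.seed, rep, fold)
            fit_settings = SAEMSettings(
                n_iter=settings.n_iter,
                n_burn=settings.n_burn,
                sa_exponent=settings.sa_exponent,
                mh_inner=settings.mh_inner,
                proposal_scale=settings.proposal_scale,
                adapt_target=settings.adapt_target,
                seed=seed,
            )
            result = fit(train_ds, spec, train_kin, fit_settings)
            mp_settings = map_iter if map_iter is not None else map_settings()
            mp_settings = SAEMSettings(
                n_iter=mp_settings.n_iter,
                n_burn=mp_settings.n_burn,
                sa_exponent=mp_settings.sa_exponent,
                mh_inner=mp_settings.mh_inner,
                proposal_scale=mp_settings.proposal_scale,
                adapt_target=mp_settings.adapt_target,
                seed=seed + 1,
            )
            mp = map_u(train_ds, spec, train_kin, result.theta, mp_settings)

            q = spec.q
            u_mat = mp.effects_matrix(q)
            if plan.scenario == "cv1":
                new_vars, u_new = extend_u(kinship, train_vars, mp.u_hat, q)
                all_vars = train_vars + new_vars
                u_all = np.vstack([u_mat, u_new])
            else:
                all_vars = train_vars
                u_all = u_mat

            val_ds = dataset.subset(val_ix)
            phi_hat = predict_phi(val_ds, spec, result.theta, u_all, all_vars)
            for local_i, global_i in enumerate(val_ix):
                rec = dataset.plants[global_i]
                cond = (
                    rec.covariates.get(plan.env_covariate)
                    if plan.env_covariate
                    else None
                )
                y_hat = curve.evaluate(phi_hat[local_i], rec.times)
                rel_y = relative_difference(y_hat, rec.values) if np.any(
                    rec.values != 0
                ) else np.full(rec.n_obs, np.nan)
                for j in range(rec.n_obs):
                    rows.append(
                        (plan.scenario, rep, fold, rec.plant_id, rec.variety,
                         cond, "y", f"t={rec.times[j]:g}", float(rec.times[j]),
                         float(y_hat[j]), float(rec.values[j]), float(rel_y[j]))
                    )
                if truth_phi is not None:
                    rel_p = relative_difference(
                        phi_hat[local_i], truth_phi[global_i]
                    )
                    for j in range(phi_hat.shape[1]):
                        rows.append(
                            (plan.scenario, rep, fold, rec.plant_id, rec.variety,
                             cond, "phi", f"phi{j + 1}", np.nan,
                             float(phi_hat[local_i, j]),
                             float(truth_phi[global_i, j]), float(rel_p[j]))
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario", "rep", "fold", "plant_id", "variety", "condition",
            "kind", "index", "time", "predicted", "reference",
            "relative_difference",
        ],
    )
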