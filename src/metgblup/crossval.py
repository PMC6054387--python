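"""Five-fold, multi-repeat cross-validation with the M_CV and S_CV schemes.

Lines (not records) are partitioned into k folds; the same partitions are
reused across every model / structure / method so all comparisons share
training and validation sets.

- **M_CV** (multiple-environment CV): a fold's lines are held out in every
  environment — the classic "new line" scenario.
- **S_CV** (single-environment CV): a fold's lines are held out in one
  target environment only; their records from the other environments stay
  in the training set, mimicking a line tested in some environments but
  missing in another. Multivariate predictions for the held-out cells
  therefore borrow the line's own records from the other environments.

Prediction ability is the Pearson correlation between observed phenotypes
and predicted GEBVs, computed within one environment by pooling the k
folds of a repeat; reports carry the mean and standard deviation over
repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .covstruct import build_covariance
from .exceptions import ModelError, UndefinedCorrelationError
from .gibbs import point_gebv, run_mcmc
from .grm import KinshipMatrix
from .models import METDesign, RotatedSolver, build_design
from .reml import assemble_init, reml_fit, univariate_components

__all__ = [
    "FoldPlan",
    "CVReport",
    "make_folds",
    "split_mcv",
    "split_scv",
    "prediction_ability",
    "run_cv",
]

logger = logging.getLogger("metgblup.crossval")


@dataclass(frozen=True)
class FoldPlan:
    """One fold of one repeat: the full line partition plus which fold is
    the validation set, the scheme, and (for S_CV) the target environment."""

    repeat: int
    fold: int
    partition: tuple[tuple[str, ...], ...]
    scheme: str = "M_CV"
    target_env: str | None = None
    seed: int = 0

    @property
    def validation_lines(self) -> tuple[str, ...]:
        return self.partition[self.fold]

    @property
    def training_lines(self) -> tuple[str, ...]:
        return tuple(
            s for j, f in enumerate(self.partition) if j != self.fold for s in f
        )


def make_folds(
    line_ids: list[str],
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    scheme: str = "M_CV",
    target_env: str | None = None,
) -> list[FoldPlan]:
    """Random balanced partitions of lines into k folds, one partition per
    repeat; fold sizes differ by at most one. Deterministic given seed."""
    n = len(line_ids)
    if n < k:
        raise ModelError(f"cannot split {n} lines into {k} folds")
    if scheme not in ("M_CV", "S_CV"):
        raise ModelError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        parts = tuple(
            tuple(line_ids[i] for i in chunk) for chunk in np.array_split(perm, k)
        )
        for fold in range(k):
            plans.append(
                FoldPlan(rep, fold, parts, scheme=scheme, target_env=target_env, seed=seed)
            )
    return plans


def _check_records(phenotypes: pd.DataFrame) -> pd.DataFrame:
    ph = phenotypes.copy()
    ph["line"] = ph["line"].astype(str)
    ph["env"] = ph["env"].astype(str)
    ph = ph.dropna(subset=["value"])
    return ph


def split_mcv(plan: FoldPlan, phenotypes: pd.DataFrame):
    """M_CV: validation = every observed record of the fold lines (all
    environments); training = all records of the other lines."""
    if plan.scheme != "M_CV":
        raise ModelError(f"plan scheme is {plan.scheme}, expected M_CV")
    ph = _check_records(phenotypes)
    in_fold = ph["line"].isin(plan.validation_lines)
    train, val = ph[~in_fold], ph[in_fold]
    if train.empty or train["env"].nunique() < ph["env"].nunique():
        raise ModelError("an environment has no training records")
    return train.reset_index(drop=True), val.reset_index(drop=True)


def split_scv(plan: FoldPlan, phenotypes: pd.DataFrame):
    """S_CV: validation = the fold lines' records in the target environment
    only; everything else (including those lines' other environments) is
    training."""
    if plan.scheme != "S_CV":
        raise ModelError(f"plan scheme is {plan.scheme}, expected S_CV")
    if plan.target_env is None:
        raise ModelError("S_CV plan needs a target_env")
    ph = _check_records(phenotypes)
    is_val = ph["line"].isin(plan.validation_lines) & (ph["env"] == plan.target_env)
    train, val = ph[~is_val], ph[is_val]
    if train.empty:
        raise ModelError("empty training set")
    return train.reset_index(drop=True), val.reset_index(drop=True)


def prediction_ability(observed, predicted) -> float:
    """Sample Pearson correlation between observed phenotypes and GEBVs."""
    x = np.asarray(observed, float)
    y = np.asarray(predicted, float)
    if x.shape != y.shape or x.size < 3:
        raise ModelError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ModelError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# CV driver
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-repeat prediction abilities and their aggregation."""

    results: pd.DataFrame  # env, model, structure, scheme, method, repeat, ability
    n_repeats: int
    n_failures: int = 0

    def summary(self) -> pd.DataFrame:
        g = self.results.groupby(
            ["scheme", "model", "structure", "method", "env"], sort=False
        )["ability"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out

    def table(self) -> pd.DataFrame:
        """Rows = scheme x model x structure (x method), columns = env,
        cells formatted 'mean (sd)'."""
        s = self.summary()
        s["cell"] = s.apply(lambda r: f"{r['mean']:.2f} ({r['std']:.2f})", axis=1)
        return s.pivot_table(
            index=["method", "scheme", "model", "structure"],
            columns="env",
            values="cell",
            aggfunc="first",
        )

    def mean_ability(self, **filters) -> float:
        df = self.results
        for key, val in filters.items():
            df = df[df[key] == val]
        return float(df["ability"].mean())


def _chain_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _gebv_lookup(gebv: np.ndarray, line_ids, env_ids, records: pd.DataFrame):
    li = {s: i for i, s in enumerate(line_ids)}
    ei = {s: e for e, s in enumerate(env_ids)}
    return np.array(
        [gebv[li[r.line], ei[r.env]] for r in records.itertuples()]
    )


def run_cv(
    phenotypes: pd.DataFrame,
    K: KinshipMatrix,
    models=(1,),
    structures=("US",),
    method: str = "reml",
    schemes=("M_CV",),
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    mcmc_iters: int = 10_000,
    mcmc_burnin: int = 3_000,
    mcmc_thin: int = 10,
) -> CVReport:
    """Cross-validated prediction abilities for every requested
    model x structure x scheme combination, all sharing the same folds.

    Validation phenotypes are removed before any variance-component
    estimation. Model 3 trains and validates per environment independently
    (the univariate 'RND' protocol) and ignores the scheme distinction.
    Failed fits are logged, counted and excluded from aggregation.
    """
    if method not in ("reml", "mcmc"):
        raise ModelError(f"unknown method {method!r}")
    models = [models] if np.isscalar(models) else list(models)
    structures = [structures] if isinstance(structures, str) else list(structures)
    schemes = [schemes] if isinstance(schemes, str) else list(schemes)
    ph = _check_records(phenotypes)
    env_ids = list(dict.fromkeys(ph["env"]))
    line_ids = list(K.line_ids)
    base_plans = make_folds(line_ids, k=k, n_repeats=n_repeats, seed=seed)

    rows = []
    failures = 0
    # univariate warm starts depend only on the training split, so they are
    # shared across models and structures
    uni_cache: dict = {}
    for model in models:
        model_structs = structures if model == 1 else ["IDV"] if model in (2, 3) else []
        for structure in model_structs:
            for scheme in schemes if model != 3 else ["M_CV"]:
                preds = {
                    (rep, env): ([], [])
                    for rep in range(n_repeats)
                    for env in env_ids
                }
                for plan in base_plans:
                    tasks = (
                        [replace(plan, scheme="S_CV", target_env=te) for te in env_ids]
                        if scheme == "S_CV"
                        else [plan]
                    )
                    for task in tasks:
                        try:
                            got = _fit_predict(
                                task, ph, K, model, structure, method, env_ids,
                                line_ids, seed, mcmc_iters, mcmc_burnin, mcmc_thin,
                                uni_cache,
                            )
                        except (ModelError, np.linalg.LinAlgError) as exc:
                            failures += 1
                            logger.warning(
                                "fit failed (model=%s %s %s rep=%d fold=%d): %s",
                                model, structure, task.scheme, task.repeat,
                                task.fold, exc,
                            )
                            continue
                        for env, obs, pred in got:
                            preds[(task.repeat, env)][0].extend(obs)
                            preds[(task.repeat, env)][1].extend(pred)
                for (rep, env), (obs, pred) in preds.items():
                    if len(obs) < 3:
                        continue
                    try:
                        r = prediction_ability(obs, pred)
                    except UndefinedCorrelationError:
                        r = np.nan
                        logger.warning("undefined correlation: env=%s rep=%d", env, rep)
                    rows.append(
                        {
                            "env": env,
                            "model": model,
                            "structure": structure if model == 1 else "IDV",
                            "scheme": scheme if model != 3 else "RND",
                            "method": method,
                            "repeat": rep,
                            "ability": r,
                        }
                    )
    results = pd.DataFrame(rows)
    if not results.empty:
        results = results.dropna(subset=["ability"])
    return CVReport(results=results, n_repeats=n_repeats, n_failures=failures)


def _fit_predict(
    plan, ph, K, model, structure, method, env_ids, line_ids, seed,
    mcmc_iters, mcmc_burnin, mcmc_thin, uni_cache=None,
):
    """Fit one training split and return [(env, observed, predicted)]."""
    if uni_cache is None:
        uni_cache = {}
    if plan.scheme == "S_CV":
        train, val = split_scv(plan, ph)
    else:
        train, val = split_mcv(plan, ph)
    if val.empty:
        return []

    if model == 3:
        out = []
        for env in env_ids:
            tr_e = train[train["env"] == env]
            va_e = val[val["env"] == env]
            if va_e.empty:
                continue
            tr_lines = [s for s in line_ids if s in set(tr_e["line"])]
            design = build_design(tr_e, tr_lines, 3, env_ids=[env])
            res = reml_fit(design, K.subset(tr_lines))
            solver = RotatedSolver(design, K.subset(tr_lines))
            beta, s_r, _ = solver.gls(
                res.vc_hat.effective_G0(), np.array([[res.vc_hat.sigma_e2]])
            )
            li = {s: i for i, s in enumerate(K.line_ids)}
            cross = K.values[np.ix_([li[s] for s in va_e["line"]],
                                    [li[s] for s in tr_lines])]
            pred = solver.predict_new_lines(res.vc_hat, cross, beta, s_r)[:, 0]
            out.append((env, list(va_e["value"]), list(pred)))
        return out

    if method == "mcmc":
        # all lines stay in the design; validation cells are simply absent
        # and get data-augmented, so GEBVs come out for every cell
        design = build_design(train, line_ids, model, env_ids=env_ids)
        chain = run_mcmc(
            design, K, structure, n_iter=mcmc_iters, burnin=mcmc_burnin,
            thin=mcmc_thin,
            seed=_chain_seed(seed, plan.repeat, plan.fold,
                             env_ids.index(plan.target_env) if plan.target_env else 0,
                             model, hash(structure) % 1000),
        )
        gebv = point_gebv(chain)
        pred = _gebv_lookup(gebv, line_ids, env_ids, val)
        return _group_by_env(val, pred, env_ids)

    # REML path
    cache_key = (plan.scheme, plan.repeat, plan.fold, plan.target_env)
    if plan.scheme == "M_CV":
        tr_lines = [s for s in line_ids if s not in set(plan.validation_lines)]
        design = build_design(train, tr_lines, model, env_ids=env_ids)
        K_tr = K.subset(tr_lines)
        if cache_key not in uni_cache:
            uni_cache[cache_key] = univariate_components(design, K_tr)
        init = assemble_init(model, *uni_cache[cache_key], structure)
        res = reml_fit(design, K_tr, structure, init=init)
        solver = RotatedSolver(design, K_tr)
        beta, s_r, _ = solver.gls(
            res.vc_hat.effective_G0(), build_covariance(res.vc_hat.R0)
        )
        li = {s: i for i, s in enumerate(K.line_ids)}
        va_lines = list(dict.fromkeys(val["line"]))
        cross = K.values[np.ix_([li[s] for s in va_lines],
                                [li[s] for s in tr_lines])]
        gebv_val = solver.predict_new_lines(res.vc_hat, cross, beta, s_r)
        pred = _gebv_lookup(gebv_val, va_lines, env_ids, val)
    else:
        design = build_design(train, line_ids, model, env_ids=env_ids)
        if cache_key not in uni_cache:
            uni_cache[cache_key] = univariate_components(design, K)
        init = assemble_init(model, *uni_cache[cache_key], structure)
        res = reml_fit(design, K, structure, init=init)
        pred = _gebv_lookup(res.fit.gebv, line_ids, env_ids, val)
    return _group_by_env(val, pred, env_ids)


def _group_by_env(val: pd.DataFrame, pred: np.ndarray, env_ids):
    out = []
    for env in env_ids:
        sel = (val["env"] == env).to_numpy()
        if sel.any():
            out.append((env, list(val["value"][sel]), list(pred[sel])))
    return out
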