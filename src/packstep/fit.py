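"""Stratified conditional-likelihood estimation and the BIC model ladder.

Each stratum is one used step plus its control steps; the per-stratum
intercept that absorbs availability cancels out of the conditional
probability that the used row was the one chosen, leaving the exact
conditional (multinomial-logit) likelihood

    sum_strata [ beta' x_used  -  log sum_rows exp(beta' x_row) ].

This is the same maximizer the Poisson-device formulation with
per-stratum intercepts targets for fixed effects; the conditional form
is the primary estimator here because it is a small, stable, convex
optimization (Newton with analytic gradient and Hessian).

Inter-pack heterogeneity in selection terms is handled by a two-stage
estimator: per-pack conditional fits, then per-term inverse-variance
pooling with a DerSimonian-Laird between-pack variance.

Model comparison uses BIC = -2 logLik + n_params ln(n_strata), with the
number of strata (conditional contributions) as the sample size.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

log = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """A term list: fixed movement modifiers and random selection terms.

    ``random`` terms get per-pack slopes under the two-stage estimator;
    under the pooled estimator the distinction only affects reporting.
    A term may not appear in both lists.
    """

    name: str
    fixed: list[str] = field(default_factory=list)
    random: list[str] = field(default_factory=list)

    def __post_init__(self):
        dup = set(self.fixed) & set(self.random)
        if dup:
            raise ValueError(f"terms both fixed and random: {sorted(dup)}")

    @property
    def terms(self) -> list[str]:
        return list(self.fixed) + list(self.random)

    @property
    def n_params(self) -> int:
        return len(self.terms)


@dataclass
class FitResult:
    """Estimates on the standardized scale, with uncertainty and BIC."""

    spec: ModelSpec
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_strata: int
    n_dropped: int
    converged: bool
    n_iter: int
    method: str = "pooled"
    between_pack_var: dict[str, float] | None = None
    per_pack: pd.DataFrame | None = None

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.spec.n_params * np.log(self.n_strata)

    def coef(self, term: str) -> float:
        return float(self.estimates[self.spec.terms.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se[self.spec.terms.index(term)])

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "term": self.spec.terms,
                "estimate": self.estimates,
                "se": self.se,
            }
        )
        if self.between_pack_var:
            df["between_pack_var"] = [
                self.between_pack_var.get(t, np.nan) for t in self.spec.terms
            ]
        return df


def build_design_arrays(
    table: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design table -> (X[S, R, p], used-row index[S], n_dropped).

    Strata with a missing value for any term (in any row) are excluded
    and counted.  All retained strata must share the same row count and
    hold exactly one used row.
    """
    missing = [t for t in terms if t not in table.columns]
    if missing:
        raise KeyError(f"terms not in design table: {missing}")
    sizes = table.groupby("stratum_id").size()
    if sizes.nunique() != 1:
        # unequal strata can only come from upstream filtering bugs
        raise ValueError("strata have unequal row counts")
    R = int(sizes.iloc[0])
    tab = table.sort_values(["stratum_id", "y"], ascending=[True, False])
    X = tab[terms].to_numpy(float).reshape(-1, R, len(terms))
    y = tab["y"].to_numpy(float).reshape(-1, R)
    if not np.all(y.sum(axis=1) == 1):
        raise ValueError("each stratum must contain exactly one used row")
    ok = np.isfinite(X).all(axis=(1, 2))
    used_idx = y.argmax(axis=1)
    return X[ok], used_idx[ok], int((~ok).sum())


def conditional_loglik(X: np.ndarray, used_idx: np.ndarray, beta: np.ndarray) -> float:
    """Exact stratified conditional log-likelihood (log-sum-exp safe)."""
    s = X @ beta
    used = s[np.arange(len(s)), used_idx]
    return float(np.sum(used - logsumexp(s, axis=1)))


def _loglik_grad_hess(X, used_idx, beta):
    s = X @ beta  # (S, R)
    smax = s.max(axis=1, keepdims=True)
    w = np.exp(s - smax)
    denom = w.sum(axis=1, keepdims=True)
    p = w / denom  # softmax per stratum
    used = s[np.arange(len(s)), used_idx]
    ll = float(np.sum(used - (np.log(denom[:, 0]) + smax[:, 0])))
    xbar = np.einsum("sr,srp->sp", p, X)
    x_used = X[np.arange(len(X)), used_idx]
    grad = (x_used - xbar).sum(axis=0)
    exx = np.einsum("sr,srp,srq->pq", p, X, X)
    hess = -(exx - xbar.T @ xbar)
    return ll, grad, hess


def fit_fixed(
    table: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_strata_per_param: int = 10,
) -> FitResult:
    """Maximize the conditional likelihood by damped Newton from beta=0.

    Standard errors come from the inverse observed information.
    Non-convergence and likely separation (runaway coefficients) are
    flagged on the result, never silent.
    """
    terms = spec.terms
    X, used_idx, n_dropped = build_design_arrays(table, terms)
    S, _, p = X.shape
    if S < min_strata_per_param * p:
        raise ValueError(
            f"{S} usable strata < sanity floor of {min_strata_per_param} per parameter "
            f"({p} parameters)"
        )
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(X, used_idx, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = grad * 1e-3  # singular Hessian: tiny gradient ascent
        # damped Newton: halve until the likelihood does not decrease
        alpha = 1.0
        for _ in range(40):
            cand = beta + alpha * step
            ll_new = conditional_loglik(X, used_idx, cand)
            if ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        ll, grad, hess = _loglik_grad_hess(X, used_idx, beta)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 50:
        warnings.warn(
            f"model {spec.name!r}: runaway coefficient (possible separation)",
            stacklevel=2,
        )
        converged = False
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
        converged = False
    return FitResult(
        spec=spec,
        estimates=beta,
        se=se,
        cov=cov,
        loglik=ll,
        n_strata=S,
        n_dropped=n_dropped,
        converged=converged,
        n_iter=it,
    )


def _dersimonian_laird(b: np.ndarray, se: np.ndarray) -> tuple[float, float, float]:
    """DL pooling: (pooled mean, pooled SE, between-group variance)."""
    w = 1.0 / se**2
    mu_fe = np.sum(w * b) / np.sum(w)
    q = np.sum(w * (b - mu_fe) ** 2)
    k = len(b)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    mu = np.sum(w_star * b) / np.sum(w_star)
    return float(mu), float(1.0 / np.sqrt(np.sum(w_star))), float(tau2)


def fit_random(
    table: pd.DataFrame,
    spec: ModelSpec,
    min_strata_per_param: int = 5,
) -> FitResult:
    """Two-stage estimator for inter-pack variability in selection.

    Stage one fits the conditional likelihood per pack; stage two pools
    each term across packs by DerSimonian-Laird inverse-variance
    weighting, giving a population mean, its SE, and a between-pack
    variance for every term designated random.  Packs whose fit fails
    are excluded from pooling and reported.
    """
    packs = sorted(table["pack_id"].unique())
    if len(packs) < 3:
        raise ValueError("two-stage random-effects fit needs >= 3 packs")
    per_pack_rows = []
    fits = {}
    for pack in packs:
        sub = table[table["pack_id"] == pack]
        try:
            res = fit_fixed(
                sub, spec, min_strata_per_param=min_strata_per_param
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            log.warning("pack %s excluded from pooling: %s", pack, err)
            continue
        if not res.converged or not np.all(np.isfinite(res.se)):
            log.warning("pack %s fit did not converge; excluded", pack)
            continue
        fits[pack] = res
        for t, b, s in zip(spec.terms, res.estimates, res.se):
            per_pack_rows.append(
                {"pack_id": pack, "term": t, "estimate": b, "se": s}
            )
    if len(fits) < 2:
        raise ValueError("fewer than two packs produced usable fits")
    per_pack = pd.DataFrame(per_pack_rows)
    estimates, ses, tau2 = [], [], {}
    for t in spec.terms:
        sub = per_pack[per_pack["term"] == t]
        mu, se, t2 = _dersimonian_laird(
            sub["estimate"].to_numpy(), sub["se"].to_numpy()
        )
        estimates.append(mu)
        ses.append(se)
        if t in spec.random:
            tau2[t] = t2
    estimates = np.asarray(estimates)
    ses = np.asarray(ses)
    X, used_idx, n_dropped = build_design_arrays(table, spec.terms)
    ll = conditional_loglik(X, used_idx, estimates)
    return FitResult(
        spec=spec,
        estimates=estimates,
        se=ses,
        cov=np.diag(ses**2),
        loglik=ll,
        n_strata=len(X),
        n_dropped=n_dropped,
        converged=True,
        n_iter=0,
        method="two-stage",
        between_pack_var=tau2,
        per_pack=per_pack,
    )


def load_model_config(path) -> tuple[list[ModelSpec], "LadderConfig"]:
    """Read a declarative JSON model config.

    The file holds ``{"models": [{"name", "fixed", "random"}, ...],
    "ladder": {<LadderConfig fields>}}``; either key may be absent.
    """
    import json

    with open(path) as fh:
        raw = json.load(fh)
    specs = [
        ModelSpec(
            name=m["name"],
            fixed=list(m.get("fixed", [])),
            random=list(m.get("random", [])),
        )
        for m in raw.get("models", [])
    ]
    ladder_raw = raw.get("ladder", {})
    ladder = LadderConfig(**ladder_raw)
    return specs, ladder


# ---------------------------------------------------------------------------
# the four-stage model-selection ladder


@dataclass
class LadderConfig:
    """Finite candidate grammars for the four selection stages."""

    landcover_terms: list[str] = field(
        default_factory=lambda: ["dist_pans", "dist_grassland", "dist_roads"]
    )
    movement_terms: list[str] = field(
        default_factory=lambda: [
            "step_length_km",
            "log_sl:daytime",
            "log_sl:nighttime",
            "log_sl:crepuscular",
            "cos_ta:denning",
            "cos_ta:predenning",
            "cos_ta:postdenning",
        ]
    )
    windows: tuple = (7, 14, 30, 90)
    levels: tuple = (50, 95)
    include_dist_to_neigh: bool = True
    max_random_effects: int = 2
    stage3_landcover: list[str] = field(
        default_factory=lambda: ["dist_pans", "dist_roads", "dist_grassland"]
    )
    stage3_movement: list[str] = field(default_factory=lambda: ["log_sl", "cos_ta"])
    stage4_social: dict[str, list[str]] = field(
        default_factory=lambda: {
            "pack_size": ["a_diff_mean", "neigh_a_mean", "a_ratio"],
            "pup_presence": ["p", "neigh_p"],
            "pack_tenure": ["e"],
        }
    )
    estimator: str = "pooled"  # 'pooled' | 'two-stage'


@dataclass
class LadderReport:
    """Per-stage BIC tables and winners."""

    tables: dict[str, pd.DataFrame]
    winners: dict[str, ModelSpec]
    fits: dict[str, FitResult]
    improving_social: pd.DataFrame | None = None


def _fit_candidates(table, specs, estimator) -> tuple[pd.DataFrame, dict]:
    rows, fits = [], {}
    fitter = fit_random if estimator == "two-stage" else fit_fixed
    for spec in specs:
        try:
            res = fitter(table, spec)
        except (ValueError, KeyError, np.linalg.LinAlgError) as err:
            rows.append(
                {"model": spec.name, "n_params": spec.n_params, "bic": np.nan,
                 "loglik": np.nan, "converged": False, "note": str(err)}
            )
            continue
        fits[spec.name] = res
        rows.append(
            {"model": spec.name, "n_params": spec.n_params, "bic": res.bic,
             "loglik": res.loglik, "converged": res.converged, "note": ""}
        )
    df = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    return df, fits


def _winner(df: pd.DataFrame, fits: dict) -> str:
    ok = df[df["converged"] & np.isfinite(df["bic"])]
    if ok.empty:
        raise RuntimeError("no candidate converged")
    return str(ok.iloc[0]["model"])


def _ensure_interaction(table, a, b):
    name = f"{a}:{b}"
    if name not in table.columns:
        table[name] = table[a].to_numpy(float) * table[b].to_numpy(float)
    return table, name


def run_ladder(
    table: pd.DataFrame,
    config: LadderConfig | None = None,
    stages: tuple = (1, 2, 3, 4),
) -> LadderReport:
    """Run the staged BIC model-selection ladder.

    Stage 1 picks a base model (<= ``max_random_effects`` landcover
    selection terms plus the movement modifiers).  Stage 2 adds one
    *own* and, separately, one *neighbor* territorial term over the
    window x level grid and keeps the min-BIC member of each set (the
    base model competes in both sets).  Stage 3 combines base + best
    own + best neighbor and tries one territorial x landcover or
    territorial(begin-of-step) x movement interaction.  Stage 4 adds
    one social x territorial (or social x movement) interaction and
    reports every candidate that beats the stage-3 winner, plus the
    best model per social category.
    """
    config = config or LadderConfig()
    table = table.copy()
    est = config.estimator
    tables: dict[str, pd.DataFrame] = {}
    winners: dict[str, ModelSpec] = {}
    all_fits: dict[str, FitResult] = {}

    movement = [
        t
        for t in config.movement_terms
        if t in table.columns and np.nanstd(table[t].to_numpy(float)) > 0
    ]

    # ---- stage 1: base candidates
    specs = []
    lc = [t for t in config.landcover_terms if t in table.columns]
    combos = [
        c
        for r in range(1, config.max_random_effects + 1)
        for c in itertools.combinations(lc, r)
    ]
    for combo in combos:
        specs.append(
            ModelSpec(name="base:" + "+".join(combo), fixed=movement, random=list(combo))
        )
    df1, fits1 = _fit_candidates(table, specs, est)
    tables["stage1"] = df1
    all_fits.update(fits1)
    base_name = _winner(df1, fits1)
    base = fits1[base_name].spec
    winners["stage1"] = base
    if 2 not in stages:
        return LadderReport(tables=tables, winners=winners, fits=all_fits)

    # ---- stage 2: own and neighbor territorial scales
    def terr_candidates(side):
        names = [
            f"dist_{w}_{side}_{lv}"
            for w in config.windows
            for lv in config.levels
        ]
        if side == "neigh" and config.include_dist_to_neigh:
            names.append("dist_to_neigh")
        return [n for n in names if n in table.columns]

    stage2_best = {}
    for side in ("own", "neigh"):
        specs = [ModelSpec(name=f"{side}:base", fixed=base.fixed, random=base.random)]
        for term in terr_candidates(side):
            specs.append(
                ModelSpec(
                    name=f"{side}:{term}",
                    fixed=base.fixed,
                    random=base.random + [term],
                )
            )
        df, fits = _fit_candidates(table, specs, est)
        tables[f"stage2_{side}"] = df
        all_fits.update(fits)
        win = _winner(df, fits)
        winners[f"stage2_{side}"] = fits[win].spec
        added = [t for t in fits[win].spec.random if t not in base.random]
        stage2_best[side] = added[0] if added else None
    if 3 not in stages:
        return LadderReport(tables=tables, winners=winners, fits=all_fits)

    # ---- stage 3: global territorial model with one interaction
    terr_terms = [t for t in stage2_best.values() if t]
    g_random = base.random + terr_terms
    specs = [ModelSpec(name="global:none", fixed=base.fixed, random=g_random)]
    for terr in terr_terms:
        for lcov in config.stage3_landcover:
            if lcov not in table.columns:
                continue
            table, name = _ensure_interaction(table, terr, lcov)
            specs.append(
                ModelSpec(name=f"global:{name}", fixed=base.fixed + [name], random=g_random)
            )
        start_col = f"{terr}_start"
        if start_col in table.columns:
            for mov in config.stage3_movement:
                if mov not in table.columns:
                    continue
                table, name = _ensure_interaction(table, start_col, mov)
                specs.append(
                    ModelSpec(
                        name=f"global:{name}", fixed=base.fixed + [name], random=g_random
                    )
                )
    df3, fits3 = _fit_candidates(table, specs, est)
    tables["stage3"] = df3
    all_fits.update(fits3)
    g_name = _winner(df3, fits3)
    g_spec = fits3[g_name].spec
    winners["stage3"] = g_spec
    if 4 not in stages:
        return LadderReport(tables=tables, winners=winners, fits=all_fits)

    # ---- stage 4: global social candidates
    specs = []
    categories = {}
    season_cols = []
    for terr in terr_terms:
        for season in ("denning", "predenning", "postdenning"):
            col = f"{terr}:season_{season}"
            if col not in table.columns:
                table[col] = np.where(
                    table["season"] == season, table[terr].to_numpy(float), 0.0
                )
            season_cols.append(col)
        name = f"{terr}xseason"
        specs.append(
            ModelSpec(
                name=f"social:{name}",
                fixed=g_spec.fixed + [c for c in season_cols if c.startswith(terr)],
                random=g_spec.random,
            )
        )
        categories[f"social:{name}"] = "seasonality"
    for category, socials in config.stage4_social.items():
        for soc in socials:
            if soc not in table.columns:
                continue
            for terr in terr_terms:
                table, name = _ensure_interaction(table, terr, soc)
                mname = f"social:{name}"
                specs.append(
                    ModelSpec(name=mname, fixed=g_spec.fixed + [name], random=g_spec.random)
                )
                categories[mname] = category
            for mov in ("log_sl", "cos_ta"):
                if mov not in table.columns:
                    continue
                table, name = _ensure_interaction(table, soc, mov)
                mname = f"social:{name}"
                specs.append(
                    ModelSpec(name=mname, fixed=g_spec.fixed + [name], random=g_spec.random)
                )
                categories[mname] = category
    df4, fits4 = _fit_candidates(table, specs, est)
    df4["category"] = df4["model"].map(categories)
    g_bic = all_fits[g_name].bic
    df4["beats_global_territorial"] = df4["bic"] < g_bic
    tables["stage4"] = df4
    all_fits.update(fits4)
    improving = df4[df4["beats_global_territorial"] & df4["converged"]]
    best_per_cat = (
        improving.sort_values("bic").groupby("category").head(1)
        if not improving.empty
        else improving
    )
    if not improving.empty:
        winners["stage4"] = fits4[str(improving.iloc[0]["model"])].spec
    return LadderReport(
        tables=tables,
        winners=winners,
        fits=all_fits,
        improving_social=best_per_cat,
    )
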