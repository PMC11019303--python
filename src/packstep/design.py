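"""The stratified used/control design.

Each observed (used) step is matched with ``n_controls`` control steps
sampled from a *tentative* movement kernel — gamma step lengths and
von Mises turning angles fitted to the observed movement data — giving
one stratum of 21 rows (by default) per pack-step.  Selection
covariates are evaluated at each row's end-of-step location; territorial
movement modifiers at the stratum's shared begin-of-step location;
social covariates join by the nearest sighting within 40 days.
Covariates are standardized with pooled moments and screened for
collinearity at ``|r| < 0.6``.

The design table (one row per used/control point) is the pipeline's
central interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


# ---------------------------------------------------------------------------
# tentative movement kernel


@dataclass
class TentativeKernel:
    """Gamma step-length (km) and zero-mean von Mises turn kernel."""

    shape: float  # gamma shape k0
    scale: float  # gamma scale theta0, km
    kappa: float  # von Mises concentration (0 = uniform turns)

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0 or self.kappa < 0:
            raise ValueError("gamma parameters must be > 0 and kappa >= 0")

    @property
    def mean_step_km(self) -> float:
        return self.shape * self.scale

    def sample(self, n: int, rng: np.random.Generator):
        """Draw ``n`` (length_km, turn_angle) pairs."""
        lengths = rng.gamma(self.shape, self.scale, size=n)
        if self.kappa > 0:
            turns = rng.vonmises(0.0, self.kappa, size=n)
        else:
            turns = rng.uniform(-np.pi, np.pi, size=n)
        return lengths, turns


def _vonmises_kappa_mle(turns: np.ndarray) -> float:
    """Concentration MLE for a zero-mean von Mises sample.

    Solves I1(k)/I0(k) = mean(cos(turn)); a non-positive mean resultant
    length means no directional persistence, i.e. kappa = 0.
    """
    rbar = float(np.mean(np.cos(turns)))
    if rbar <= 0:
        return 0.0

    def f(k):
        return special.i1(k) / special.i0(k) - rbar

    hi = 2.0
    while f(hi) < 0 and hi < 1e4:
        hi *= 2.0
    return float(optimize.brentq(f, 1e-12, hi))


def fit_tentative_kernel(steps: pd.DataFrame, min_steps: int = 30) -> TentativeKernel:
    """Maximum-likelihood tentative kernel from pooled complete steps."""
    complete = steps[steps["complete"]]
    if len(complete) < min_steps:
        raise ValueError(f"need >= {min_steps} complete steps, got {len(complete)}")
    lengths = complete["step_length_km"].to_numpy(float)
    lengths = lengths[lengths > 0]
    if np.ptp(lengths) == 0:
        raise ValueError("degenerate step lengths: all observed lengths identical")
    shape, _, scale = stats.gamma.fit(lengths, floc=0.0)
    turns = complete["turn_angle"].to_numpy(float)
    kappa = _vonmises_kappa_mle(turns[np.isfinite(turns)])
    return TentativeKernel(shape=float(shape), scale=float(scale), kappa=float(kappa))


# ---------------------------------------------------------------------------
# control sampling


def sample_controls(
    steps: pd.DataFrame,
    kernel: TentativeKernel,
    n_controls: int = 20,
    seed: int | None = None,
    min_length_km: float = 0.125,
) -> pd.DataFrame:
    """Build the stratified design table: 1 used + ``n_controls`` control
    rows per complete step.

    Control endpoints displace the used step's start point by a sampled
    length along (previous observed heading + sampled turn), so control
    turn cosines are the cosines of the sampled turns.  Steps without a
    defined previous heading are dropped (control placement needs it).
    """
    usable = steps[steps["complete"] & np.isfinite(steps["prev_heading"])]
    usable = usable.reset_index(drop=True)
    n = len(usable)
    if n == 0:
        raise ValueError("no complete steps with a defined previous heading")
    rng = np.random.default_rng(seed)
    lengths, turns = kernel.sample(n * n_controls, rng)
    lengths = lengths.reshape(n, n_controls)
    turns = turns.reshape(n, n_controls)
    prev = usable["prev_heading"].to_numpy()[:, None]
    headings = prev + turns
    x_end = usable["x_start"].to_numpy()[:, None] + 1000.0 * lengths * np.cos(headings)
    y_end = usable["y_start"].to_numpy()[:, None] + 1000.0 * lengths * np.sin(headings)

    stratum_ids = (
        usable["pack_id"].astype(str)
        + "|"
        + pd.DatetimeIndex(usable["t_end"]).strftime("%Y%m%dT%H%M")
    ).to_numpy()

    used = usable.copy()
    used["stratum_id"] = stratum_ids
    used["y"] = 1

    reps = np.repeat(np.arange(n), n_controls)
    ctrl = usable.iloc[reps].reset_index(drop=True)
    ctrl["stratum_id"] = stratum_ids[reps]
    ctrl["y"] = 0
    ctrl["x_end"] = x_end.ravel()
    ctrl["y_end"] = y_end.ravel()
    ctrl["step_length_km"] = lengths.ravel()
    ctrl["log_sl"] = np.log(np.maximum(lengths.ravel(), min_length_km))
    wrapped = (turns.ravel() + np.pi) % (2 * np.pi) - np.pi
    ctrl["turn_angle"] = wrapped
    ctrl["cos_ta"] = np.cos(wrapped)
    ctrl["heading"] = (headings.ravel() + np.pi) % (2 * np.pi) - np.pi

    table = pd.concat([used, ctrl], ignore_index=True)
    table = table.sort_values(["stratum_id", "y"], ascending=[True, False])
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariate attachment


def build_movement_terms(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Expand ln(step length) x time-of-day and turn-cosine x season
    into explicit interaction columns (cell-means coding: one column
    per class, zero off-class)."""
    table = table.copy()
    cols = ["step_length_km"]
    for tod in ("daytime", "nighttime", "crepuscular"):
        col = f"log_sl:{tod}"
        table[col] = np.where(table["tod"] == tod, table["log_sl"], 0.0)
        cols.append(col)
    for season in ("denning", "predenning", "postdenning"):
        col = f"cos_ta:{season}"
        table[col] = np.where(table["season"] == season, table["cos_ta"], 0.0)
        cols.append(col)
    return table, cols


def attach_covariates(
    table: pd.DataFrame,
    landscape=None,
    layers: list[str] | None = None,
    territory_source=None,
    movement_modifier_source=None,
    sightings: pd.DataFrame | None = None,
    max_sighting_gap_days: float = 40.0,
    off_extent: str = "missing",
) -> pd.DataFrame:
    """Attach selection and modifier covariates to every design row.

    * landcover distances (km) from ``landscape`` at end-of-step points;
      rows whose endpoint falls beyond the layer extent keep their
      geometry but get missing covariates (``off_extent='missing'``,
      the default — the stratum is later dropped as incomplete), or
      edge-extrapolated values (``off_extent='clamp'``, appropriate
      when the layers are defined everywhere by construction, as with
      the bundled simulator);
    * territorial covariates from ``territory_source`` (an object with
      ``values(pack_ids, timestamps, x, y) -> DataFrame``) at end-of-step
      points; the same source evaluated at the stratum's begin-of-step
      point yields ``*_start`` movement-modifier columns, identical
      across a stratum's rows by construction;
    * social covariates joined by nearest sighting within 40 days.
    """
    if off_extent not in ("missing", "clamp"):
        raise ValueError("off_extent must be 'missing' or 'clamp'")
    table = table.copy()
    if landscape is not None:
        xe = table["x_end"].to_numpy(float)
        ye = table["y_end"].to_numpy(float)
        x0, y0, x1, y1 = landscape.extent
        outside = (xe < x0) | (xe > x1) | (ye < y0) | (ye > y1)
        for layer in layers or list(landscape.layers):
            vals = landscape.sample(layer, xe, ye) / 1000.0
            if off_extent == "missing":
                vals = np.where(outside, np.nan, vals)
            table[f"dist_{layer}"] = vals
    if territory_source is not None:
        vals = territory_source.values(
            table["pack_id"].to_numpy(),
            pd.DatetimeIndex(table["t_end"]),
            table["x_end"].to_numpy(float),
            table["y_end"].to_numpy(float),
        )
        for col in vals.columns:
            table[col] = vals[col].to_numpy()
    if movement_modifier_source is not None:
        starts = table.drop_duplicates("stratum_id")
        vals = movement_modifier_source.values(
            starts["pack_id"].to_numpy(),
            pd.DatetimeIndex(starts["t_start"]),
            starts["x_start"].to_numpy(float),
            starts["y_start"].to_numpy(float),
        )
        vals = vals.add_suffix("_start")
        vals.index = starts["stratum_id"].to_numpy()
        for col in vals.columns:
            table[col] = table["stratum_id"].map(vals[col]).to_numpy()
    if sightings is not None:
        table = attach_social(table, sightings, max_sighting_gap_days)
    return table


SOCIAL_COLUMNS = [
    "a",
    "p",
    "e",
    "neigh_p",
    "neigh_a_min",
    "neigh_a_mean",
    "neigh_a_max",
    "a_diff_min",
    "a_diff_mean",
    "a_diff_max",
    "a_ratio",
]


def attach_social(
    table: pd.DataFrame,
    sightings: pd.DataFrame,
    max_gap_days: float = 40.0,
) -> pd.DataFrame:
    """Join per-pack social attributes by the nearest sighting in time.

    Columns produced (all NaN when no sighting falls within the gap):
    focal adult count ``a`` (individuals > 12 months), pup indicator
    ``p``, tenure indicator ``e`` (1 iff the step is > 2 years after the
    pack was first observed), any-neighbor pup indicator ``neigh_p``,
    neighbor adult counts and focal-minus-neighbor differences
    aggregated to min/mean/max, and ``a_ratio`` = focal adults / all
    adults in the area.  Values are constant across a stratum's rows.
    Ties between equally near sightings go to the earlier one.
    """
    table = table.copy()
    tol = pd.Timedelta(days=max_gap_days)
    sg = sightings.copy()
    sg["timestamp"] = pd.to_datetime(sg["timestamp"])
    sg["first_observed"] = pd.to_datetime(sg["first_observed"])
    packs = sorted(sg["pack_id"].unique())

    def nearest(pack, times):
        """Nearest sighting of ``pack`` within tol per time (or None)."""
        sub = sg[sg["pack_id"] == pack].sort_values("timestamp")
        if sub.empty:
            return None
        idx = np.searchsorted(sub["timestamp"].to_numpy(), times.to_numpy())
        best = np.full(len(times), -1)
        best_dt = np.full(len(times), np.inf)
        for cand in (np.clip(idx - 1, 0, len(sub) - 1), np.clip(idx, 0, len(sub) - 1)):
            dt = np.abs(times.to_numpy() - sub["timestamp"].to_numpy()[cand])
            dt_days = dt / np.timedelta64(1, "D")
            # strict improvement keeps the earlier sighting on ties
            better = dt_days < best_dt
            best[better] = cand[better]
            best_dt[better] = dt_days[better]
        ok = best_dt <= max_gap_days
        return sub, best, ok

    strata = table.drop_duplicates("stratum_id")[["stratum_id", "pack_id", "t_end"]]
    times = pd.DatetimeIndex(strata["t_end"])
    out = pd.DataFrame(index=strata["stratum_id"].to_numpy(), columns=SOCIAL_COLUMNS, dtype=float)

    per_pack = {p: nearest(p, times) for p in packs}
    for i, (sid, focal) in enumerate(zip(strata["stratum_id"], strata["pack_id"])):
        res = per_pack.get(focal)
        if res is None or not res[2][i]:
            continue
        sub, best, _ = res
        row = sub.iloc[best[i]]
        a = float(row["n_adults"])
        out.loc[sid, "a"] = a
        out.loc[sid, "p"] = float(row["pups"])
        tenure = (times[i] - row["first_observed"]) > pd.Timedelta(days=2 * 365.25)
        out.loc[sid, "e"] = float(tenure)
        neigh_a, neigh_p = [], []
        for other in packs:
            if other == focal:
                continue
            res_o = per_pack.get(other)
            if res_o is None or not res_o[2][i]:
                continue
            row_o = res_o[0].iloc[res_o[1][i]]
            neigh_a.append(float(row_o["n_adults"]))
            neigh_p.append(float(row_o["pups"]))
        if neigh_a:
            neigh_a = np.asarray(neigh_a)
            out.loc[sid, "neigh_p"] = float(np.any(np.asarray(neigh_p) > 0))
            out.loc[sid, "neigh_a_min"] = neigh_a.min()
            out.loc[sid, "neigh_a_mean"] = neigh_a.mean()
            out.loc[sid, "neigh_a_max"] = neigh_a.max()
            out.loc[sid, "a_diff_min"] = (a - neigh_a).min()
            out.loc[sid, "a_diff_mean"] = (a - neigh_a).mean()
            out.loc[sid, "a_diff_max"] = (a - neigh_a).max()
            out.loc[sid, "a_ratio"] = a / (a + neigh_a.sum())
    for col in SOCIAL_COLUMNS:
        table[col] = table["stratum_id"].map(out[col]).to_numpy()
    return table


# ---------------------------------------------------------------------------
# standardization and collinearity screening


@dataclass
class Scalers:
    """Per-covariate (mean, sd) pairs used for standardization; kept so
    fitted effects can be unscaled back to raw units (km)."""

    moments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def scale(self, name: str, x):
        mean, sd = self.moments[name]
        return (np.asarray(x, float) - mean) / sd

    def unscale(self, name: str, z):
        mean, sd = self.moments[name]
        return np.asarray(z, float) * sd + mean


def standardize_and_screen(
    table: pd.DataFrame,
    covariates: list[str],
    r_threshold: float = 0.6,
    scalers: Scalers | None = None,
) -> tuple[pd.DataFrame, list[str], Scalers, pd.DataFrame]:
    """Center/scale covariates and screen for collinearity.

    Each listed covariate is standardized by its pooled mean/SD over all
    used+control rows (or by externally supplied ``scalers``, e.g. a
    simulator's landscape-wide moments).  The raw column is kept as
    ``<name>_raw``.  Pearson correlations over rows are computed for
    every pair; for ``|r| >= r_threshold`` the later-listed member is
    excluded (list order encodes priority).  Zero-variance covariates
    are excluded outright.

    Returns (table, retained covariate names, scalers, screening report).
    """
    table = table.copy()
    scalers = scalers or Scalers()
    report_rows = []
    usable = []
    for col in covariates:
        x = table[col].to_numpy(float)
        if col in scalers.moments:
            mean, sd = scalers.moments[col]
        else:
            mean, sd = float(np.nanmean(x)), float(np.nanstd(x))
        if sd == 0 or not np.isfinite(sd):
            report_rows.append({"term": col, "action": "excluded", "reason": "zero variance"})
            continue
        scalers.moments[col] = (mean, sd)
        table[f"{col}_raw"] = x
        table[col] = (x - mean) / sd
        usable.append(col)

    # pairwise Pearson screening, keeping the earlier-listed term
    excluded = set()
    arr = {c: table[c].to_numpy(float) for c in usable}
    for i, a in enumerate(usable):
        if a in excluded:
            continue
        for b in usable[i + 1 :]:
            if b in excluded:
                continue
            xa, xb = arr[a], arr[b]
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 3:
                continue
            r = np.corrcoef(xa[ok], xb[ok])[0, 1]
            if np.abs(r) >= r_threshold:
                excluded.add(b)
                report_rows.append(
                    {"term": b, "action": "excluded", "reason": f"|r|={abs(r):.3f} with {a}"}
                )
    retained = [c for c in usable if c not in excluded]
    for c in retained:
        report_rows.append({"term": c, "action": "retained", "reason": ""})
    report = pd.DataFrame(report_rows, columns=["term", "action", "reason"])
    return table, retained, scalers, report


def add_interaction(table: pd.DataFrame, a: str, b: str) -> tuple[pd.DataFrame, str]:
    """Product column named ``a:b`` (built on the standardized scale)."""
    name = f"{a}:{b}"
    table = table.copy()
    table[name] = table[a].to_numpy(float) * table[b].to_numpy(float)
    return table, name


def write_design_table(path, table: pd.DataFrame, sep="\t") -> None:
    out = table.copy()
    for col in ("t_start", "t_end"):
        if col in out:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, sep=sep, index=False)


def read_design_table(path, sep="\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    for col in ("t_start", "t_end"):
        if col in df:
            df[col] = pd.to_datetime(df[col])
    return df
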