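"""Vanadate-sensitive ATPase activity and Michaelis-Menten analysis.

ABC transporter ATPase activity is isolated from background phosphate
release by differencing paired assays: the same membrane preparation is
measured with and without the inhibitor orthovanadate (500 uM), and

    activity = (release without vanadate) - (release with vanadate)

per substrate concentration and replicate. Negative differences are
retained (they are noise; truncating them would bias the fits upward)
and flagged.

The dose-response is fit with the Michaelis-Menten model

    v(S) = Vmax * S / (Km + S)

by nonlinear least squares with positivity bounds; standard errors come
from the curvature of the squared-error surface at the optimum
(Gauss-Newton covariance). Whole curves are compared with the
extra-sum-of-squares F-test between the pooled fit (one shared curve)
and separate fits (Vmax and Km freed per data set):

    F = ((RSS_pooled - RSS_separate) / 2) / (RSS_separate / df_separate)

with df = (2, n_A + n_B - 4). Finally, substrate specificity predicted
in silico is tabulated against the measured one as per-substrate deltas
(transporter 2 minus transporter 1) of docking score and Km.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError
from .model import CurveComparison, DoseResponse, KineticFit

log = logging.getLogger(__name__)

#: Default substrate concentration grid, uM (0-800 uM assay range).
DEFAULT_GRID = (0.0, 1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0)

MAX_ITERATIONS = 10_000
RELATIVE_TOLERANCE = 1e-8


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def vanadate_sensitive_activity(d: DoseResponse) -> pd.DataFrame:
    """Per-concentration transporter activity from paired measurements.

    Returns the data with an ``activity`` column = no-vanadate minus
    vanadate, per (concentration, replicate) pair. Unpaired rows (NaN
    in either arm) raise; negative differences are kept and logged.
    """
    df = d.data.copy()
    required = ["concentration_uM", "activity_no_vanadate", "activity_vanadate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response table missing column(s) {missing}")
    unpaired = df["activity_no_vanadate"].isna() | df["activity_vanadate"].isna()
    if unpaired.any():
        raise ValueError(
            f"{d.substrate_id}: {int(unpaired.sum())} unpaired measurement(s)"
        )
    df["activity"] = df["activity_no_vanadate"] - df["activity_vanadate"]
    n_neg = int((df["activity"] < 0).sum())
    if n_neg:
        log.warning("%s: %d negative vanadate-sensitive activities retained",
                    d.substrate_id, n_neg)
    return df


def fit_michaelis_menten(concentrations, activities) -> KineticFit:
    """Fit v = Vmax*S/(Km+S) by bounded nonlinear least squares.

    Start values: Vmax0 = max(v); Km0 = the smallest S whose activity
    reaches Vmax0/2 (median S as fallback). Requires >= 3 distinct
    positive concentrations and a non-degenerate activity vector.
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(activities, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("concentrations and activities must be equal-length 1-D")
    if np.any(s < 0):
        raise ValueError("concentrations must be >= 0")
    if len(set(s[s > 0])) < 3:
        raise FitError("need >= 3 distinct positive concentrations")
    if np.allclose(v, 0.0):
        raise FitError("all activities are zero; nothing to fit")

    vmax0 = float(np.max(v))
    order = np.argsort(s, kind="stable")
    half = s[order][v[order] >= vmax0 / 2]
    km0 = float(half[0]) if half.size and half[0] > 0 else float(np.median(s[s > 0]))

    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, s, v,
            p0=(vmax0, km0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            max_nfev=MAX_ITERATIONS,
            xtol=RELATIVE_TOLERANCE,
            ftol=RELATIVE_TOLERANCE,
            gtol=RELATIVE_TOLERANCE,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}")
    vmax, km = (float(p) for p in popt)
    if vmax <= 0 or km <= 0:
        raise FitError(f"fit collapsed to the boundary (Vmax={vmax}, Km={km})")
    resid = v - michaelis_menten(s, vmax, km)
    rss = float(resid @ resid)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    se = np.where(np.isfinite(se), se, 0.0)  # exact data: zero curvature SE
    return KineticFit(
        vmax=vmax, vmax_se=float(se[0]),
        km=km, km_se=float(se[1]),
        rss=rss, n_points=len(s),
    )


def fit_dose_response(d: DoseResponse) -> KineticFit:
    """Difference the paired arms, then fit all points (no averaging)."""
    df = vanadate_sensitive_activity(d)
    return fit_michaelis_menten(
        df["concentration_uM"].to_numpy(), df["activity"].to_numpy()
    )


def compare_curves(s_a, v_a, s_b, v_b) -> CurveComparison:
    """Extra-sum-of-squares F-test: one shared curve vs two curves.

    The pooled fit constrains Vmax and Km to be equal across data sets;
    the separate fits free both (numerator df = 2). With identical
    noiseless data RSS_separate is 0 and F is defined as 0.
    """
    fit_a = fit_michaelis_menten(s_a, v_a)
    fit_b = fit_michaelis_menten(s_b, v_b)
    s_pool = np.concatenate([np.asarray(s_a, float), np.asarray(s_b, float)])
    v_pool = np.concatenate([np.asarray(v_a, float), np.asarray(v_b, float)])
    fit_pool = fit_michaelis_menten(s_pool, v_pool)

    rss_sep = fit_a.rss + fit_b.rss
    df_num = 2  # Vmax and Km freed
    df_den = fit_a.n_points + fit_b.n_points - 4
    if df_den < 1:
        raise FitError("not enough points for a curve comparison")
    if rss_sep <= 0.0:
        return CurveComparison(0.0, df_num, df_den, 1.0)
    f_stat = ((fit_pool.rss - rss_sep) / df_num) / (rss_sep / df_den)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return CurveComparison(float(f_stat), df_num, df_den, p)


def delta_table(scores: dict, kms: dict, transporters: tuple) -> pd.DataFrame:
    """Per-substrate deltas of docking score and Km between transporters.

    Parameters
    ----------
    scores:
        substrate -> {transporter: docking score, kcal/mol}. Both
        transporters must be present for every substrate.
    kms:
        substrate -> {transporter: Km in uM, or a KineticFit}. Km-less
        (docking-only) substrates may be absent or carry None.
    transporters:
        (reference, comparison); deltas are comparison minus reference.

    Returns a table with one row per substrate (input order) and the
    per-transporter values plus delta_score and delta_km columns.
    """
    t1, t2 = transporters

    def km_value(entry):
        if entry is None:
            return np.nan
        if isinstance(entry, KineticFit):
            return entry.km
        return float(entry)

    rows = []
    for substrate, per_t in scores.items():
        if t1 not in per_t or t2 not in per_t:
            raise ValueError(
                f"{substrate}: docking scores for both {t1} and {t2} required"
            )
        km_pair = kms.get(substrate, {})
        km1, km2 = km_value(km_pair.get(t1)), km_value(km_pair.get(t2))
        rows.append({
            "substrate": substrate,
            f"score_{t1}": per_t[t1],
            f"score_{t2}": per_t[t2],
            f"km_{t1}": km1,
            f"km_{t2}": km2,
            "delta_score": per_t[t2] - per_t[t1],
            "delta_km": km2 - km1,
        })
    return pd.DataFrame(rows)


def read_dose_response(path) -> list:
    """Read a dose-response CSV into DoseResponse objects per substrate.

    Expected columns: substrate, concentration_uM, replicate,
    activity_no_vanadate, activity_vanadate.
    """
    df = pd.read_csv(path)
    required = ["substrate", "concentration_uM", "replicate",
                "activity_no_vanadate", "activity_vanadate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for substrate, group in df.groupby("substrate", sort=False):
        out.append(DoseResponse(
            substrate_id=str(substrate),
            data=group.reset_index(drop=True),
        ))
    return out


def write_dose_response(path, responses: list):
    frames = []
    for d in responses:
        df = d.data.copy()
        if "substrate" not in df.columns:
            df.insert(0, "substrate", d.substrate_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
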