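"""Force-curve mechanics: contact point, Hertz fit, hysteresis, adhesion, aggregation.

Pipeline per curve
------------------
1. ``detect_contact_point`` — joint search for the piezo contact position z0:
   for each candidate, a linear baseline is fitted to the pre-contact portion
   and the Hertz modulus refitted, and the candidate minimizing the
   whole-curve residual wins (coarse grid over sample positions, then a
   bounded golden-section refinement).  A curve whose best candidate does not
   beat the flat-baseline null (no contact anywhere) is flagged.
2. ``curve_to_force_indentation`` — F = k*deflection - baseline(z);
   indentation delta = (z - z0) - F/k (cantilever bending removed).
3. ``fit_hertz_sphere`` — closed-form least squares of F on delta^(3/2)
   through the origin inside a fractional indentation window; the slope maps
   to the Young's modulus via E = 3*s*(1 - nu^2) / (4*sqrt(R)).
4. ``compute_viscosity_index`` — dimensionless approach/withdrawal hysteresis
   ratio (loop area over approach area), a proxy for viscous dissipation.
5. ``compute_adhesion`` — magnitude of the most negative baseline-corrected
   withdrawal force (pull-off event).

Aggregation follows the sampling design: replicate -> point -> region ->
sample by successive means; group summaries are mean +- SE with the animal
(sample) as the unit of replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .types import (AdhesionMeasure, CurveBatch, ForceCurve, IndentationResult,
                    ViscosityIndex)


@dataclass
class FitOptions:
    """Knobs of the per-curve analysis.

    nu_assumed : Poisson ratio used in the Hertz relation (0.5 = incompressible,
        the convention for soft hydrated ECM).
    fit_window : fractional indentation interval used for the modulus fit,
        as (lo, hi) fractions of the maximum indentation; the default skips
        contact-point noise (<10%) and deep-indentation substrate effects (>90%).
    min_contact_points : minimum samples inside the window for a valid fit.
    r2_min : curves with a worse Hertz fit are flagged and excluded
        from aggregation.
    baseline_gap : samples just before a contact candidate excluded from the
        baseline fit (contact is gradual on soft samples).
    min_baseline_points : minimum pre-contact samples for a candidate.
    candidate_stride : coarse-grid step in samples (None = auto, ~150 candidates).
    refine : golden-section refinement of z0 between grid neighbours.
    """

    nu_assumed: float = 0.5
    fit_window: tuple[float, float] = (0.1, 0.9)
    min_contact_points: int = 20
    r2_min: float = 0.8
    baseline_gap: int = 5
    min_baseline_points: int = 10
    candidate_stride: int | None = None
    refine: bool = True


@dataclass
class ContactFit:
    """Contact point plus the linear baseline fitted left of it."""

    z0: float               # m
    baseline_offset: float  # N (at z = 0)
    baseline_slope: float   # N/m
    sse: float
    flagged: bool = False
    flag_reason: str = ""

    def baseline(self, z: np.ndarray) -> np.ndarray:
        return self.baseline_offset + self.baseline_slope * np.asarray(z)


def _linear_fit(z: np.ndarray, F: np.ndarray) -> tuple[float, float]:
    n = z.size
    sz, sf = z.sum(), F.sum()
    szz, szf = (z * z).sum(), (z * F).sum()
    den = n * szz - sz * sz
    if den <= 0:
        return float(F.mean()), 0.0
    slope = (n * szf - sz * sf) / den
    return (sf - slope * sz) / n, slope


def _hertz_objective(z: np.ndarray, F_raw: np.ndarray, k: float, z0: float,
                     i_contact: int, opts: FitOptions) -> tuple[float, float, float, float]:
    """Whole-curve SSE for a candidate contact point.

    Returns (sse, a, b, slope) with the baseline (a, b) refitted on the
    pre-contact portion and the Hertz slope refitted inside the fit window;
    slope is NaN when the candidate is infeasible.
    """
    i_base = max(0, i_contact - opts.baseline_gap)
    if i_base < opts.min_baseline_points:
        return np.inf, 0.0, 0.0, np.nan
    a, b = _linear_fit(z[:i_base], F_raw[:i_base])
    F = F_raw - (a + b * z)
    delta = (z - z0) - F / k
    contact = (z >= z0) & (delta > 0)
    if contact.sum() < opts.min_contact_points:
        return np.inf, a, b, np.nan
    dc, Fc = delta[contact], F[contact]
    dmax = dc.max()
    win = (dc >= opts.fit_window[0] * dmax) & (dc <= opts.fit_window[1] * dmax)
    if win.sum() < opts.min_contact_points:
        return np.inf, a, b, np.nan
    x = dc[win] ** 1.5
    sxx = float(x @ x)
    if sxx <= 0:
        return np.inf, a, b, np.nan
    slope = float(x @ Fc[win]) / sxx
    if slope <= 0:
        return np.inf, a, b, np.nan
    resid = F.copy()
    resid[contact] = Fc - slope * dc**1.5
    return float(resid @ resid), a, b, slope


def detect_contact_point(curve: ForceCurve, options: FitOptions | None = None) -> ContactFit:
    """Locate the contact point by joint residual minimization.

    Candidates are approach sample positions (coarse grid); for each, the
    baseline and Hertz slope are refit and the whole-curve SSE scored.  The
    best grid candidate is refined by bounded scalar minimization between its
    neighbours.  If no candidate improves on a contact-free linear fit of the
    entire approach segment, the curve is flagged as never contacting.
    """
    opts = options or FitOptions()
    curve.validate()
    z = curve.z_app_m()
    F_raw = curve.force_app_N()
    n = z.size
    if n < 50:
        raise ValueError(f"{curve.curve_id}: approach segment needs >= 50 samples")

    a0, b0 = _linear_fit(z, F_raw)
    null_resid = F_raw - (a0 + b0 * z)
    sse_null = float(null_resid @ null_resid)

    stride = opts.candidate_stride or max(1, n // 150)
    i_lo = opts.min_baseline_points + opts.baseline_gap
    i_hi = n - opts.min_contact_points
    best = (np.inf, i_lo, 0.0, 0.0)
    for i in range(i_lo, i_hi, stride):
        sse, a, b, slope = _hertz_objective(z, F_raw, curve.k, z[i], i, opts)
        if sse < best[0]:
            best = (sse, i, a, b)

    # require a clear improvement over the contact-free null: a Hertz branch
    # fitted to pure noise only ever shaves off a fraction of a percent
    if not np.isfinite(best[0]) or best[0] >= 0.95 * sse_null:
        return ContactFit(z0=math.nan, baseline_offset=a0, baseline_slope=b0,
                          sse=sse_null, flagged=True,
                          flag_reason="no contact: no candidate beats flat-baseline null")

    sse_best, i_best, a_best, b_best = best
    z0_best = z[i_best]
    if opts.refine:
        lo = z[max(i_lo, i_best - stride)]
        hi = z[min(i_hi - 1, i_best + stride)]
        if hi > lo:
            def obj(z0c: float) -> float:
                ic = int(np.searchsorted(z, z0c))
                return _hertz_objective(z, F_raw, curve.k, z0c, ic, opts)[0]
            res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            if res.fun <= sse_best:
                z0_best = float(res.x)
                ic = int(np.searchsorted(z, z0_best))
                sse_best, a_best, b_best, _ = _hertz_objective(
                    z, F_raw, curve.k, z0_best, ic, opts)
    return ContactFit(z0=float(z0_best), baseline_offset=a_best,
                      baseline_slope=b_best, sse=float(sse_best))


def curve_to_force_indentation(curve: ForceCurve, contact: ContactFit,
                               segment: str = "approach") -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected (delta, F) arrays for one segment, in SI units.

    Negative-delta (non-contact) points are retained; callers mask on
    ``delta > 0`` where contact is required.
    """
    if segment == "approach":
        z, F_raw = curve.z_app_m(), curve.force_app_N()
    elif segment == "withdrawal":
        z, F_raw = curve.z_ret_m(), curve.force_ret_N()
    else:
        raise ValueError(f"unknown segment {segment!r}")
    F = F_raw - contact.baseline(z)
    delta = (z - contact.z0) - F / curve.k
    return delta, F


def fit_hertz_sphere(delta: np.ndarray, F: np.ndarray, R: float, nu: float,
                     options: FitOptions | None = None,
                     curve_id: str = "", z0: float = math.nan,
                     baseline: tuple[float, float] = (0.0, 0.0)) -> IndentationResult:
    """Least-squares Hertz sphere fit: slope of F on delta^(3/2) -> E (Pa)."""
    opts = options or FitOptions()
    delta = np.asarray(delta, float)
    F = np.asarray(F, float)
    contact = delta > 0
    res = IndentationResult(curve_id=curve_id, z0=z0, baseline_offset=baseline[0],
                            baseline_slope=baseline[1], E=math.nan,
                            nu_assumed=nu, r_squared=math.nan,
                            fit_range=(math.nan, math.nan), n_fit_points=0)
    if contact.sum() < opts.min_contact_points:
        res.flagged, res.flag_reason = True, "too few contact points"
        return res
    dc, Fc = delta[contact], F[contact]
    dmax = float(dc.max())
    lo, hi = opts.fit_window[0] * dmax, opts.fit_window[1] * dmax
    win = (dc >= lo) & (dc <= hi)
    if win.sum() < opts.min_contact_points:
        res.flagged, res.flag_reason = True, "too few points in fit window"
        return res
    x, y = dc[win] ** 1.5, Fc[win]
    slope = float(x @ y) / float(x @ x)
    res.fit_range = (lo, hi)
    res.n_fit_points = int(win.sum())
    if slope <= 0:
        res.flagged, res.flag_reason = True, "negative Hertz slope"
        return res
    res.E = 3.0 * slope * (1.0 - nu**2) / (4.0 * math.sqrt(R))
    sse = float(((y - slope * x) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    res.r_squared = max(0.0, 1.0 - sse / sst) if sst > 0 else 0.0
    if res.r_squared < opts.r2_min:
        res.flagged, res.flag_reason = True, f"r_squared < {opts.r2_min}"
    return res


def compute_viscosity_index(delta_app: np.ndarray, F_app: np.ndarray,
                            delta_ret: np.ndarray, F_ret: np.ndarray,
                            curve_id: str = "") -> ViscosityIndex:
    """Hysteresis ratio: (approach area - withdrawal area) / approach area.

    Areas are trapezoidal integrals of the force over indentation on the
    common contact interval; negative forces are clipped to zero so the
    adhesion well does not contaminate the dissipation estimate.
    """
    out = ViscosityIndex(curve_id=curve_id, hysteresis_ratio=math.nan)

    def area(delta: np.ndarray, F: np.ndarray, dmax: float) -> float:
        order = np.argsort(delta)
        d, f = delta[order], np.clip(F[order], 0.0, None)
        m = (d >= 0) & (d <= dmax)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(f[m], d[m]))

    ca, cr = delta_app > 0, delta_ret > 0
    if not ca.any() or not cr.any():
        out.flagged, out.flag_reason = True, "no contact interval"
        return out
    dmax = min(float(delta_app[ca].max()), float(delta_ret[cr].max()))
    a_app = area(delta_app, F_app, dmax)
    if a_app <= 0:
        out.flagged, out.flag_reason = True, "zero approach area"
        return out
    out.hysteresis_ratio = (a_app - area(delta_ret, F_ret, dmax)) / a_app
    return out


def compute_adhesion(curve: ForceCurve, contact: ContactFit,
                     curve_id: str | None = None) -> AdhesionMeasure:
    """Pull-off force: |most negative baseline-corrected withdrawal force| (nN)."""
    F = curve.force_ret_N() - contact.baseline(curve.z_ret_m())
    fmin = float(F.min())
    return AdhesionMeasure(curve_id=curve_id or curve.curve_id,
                           F_adh_nN=max(0.0, -fmin) * 1e9)


# ---------------------------------------------------------------------------
# Batch analysis and aggregation
# ---------------------------------------------------------------------------

def analyze_curve(curve: ForceCurve, options: FitOptions | None = None) -> dict:
    """Run the full per-curve analysis; returns one flat result row."""
    opts = options or FitOptions()
    contact = detect_contact_point(curve, opts)
    row = {
        "curve_id": curve.curve_id, "z0_nm": math.nan, "E_Pa": math.nan,
        "r_squared": math.nan, "hysteresis_ratio": math.nan,
        "F_adh_nN": math.nan, "flagged": True, "flag_reason": "",
    }
    if contact.flagged:
        row["flag_reason"] = contact.flag_reason
        return row
    d_app, F_app = curve_to_force_indentation(curve, contact, "approach")
    fit = fit_hertz_sphere(d_app, F_app, curve.R_m, opts.nu_assumed, opts,
                           curve_id=curve.curve_id, z0=contact.z0,
                           baseline=(contact.baseline_offset, contact.baseline_slope))
    d_ret, F_ret = curve_to_force_indentation(curve, contact, "withdrawal")
    visc = compute_viscosity_index(d_app, F_app, d_ret, F_ret, curve.curve_id)
    adh = compute_adhesion(curve, contact)
    row.update(z0_nm=contact.z0 * 1e9, E_Pa=fit.E, r_squared=fit.r_squared,
               hysteresis_ratio=visc.hysteresis_ratio, F_adh_nN=adh.F_adh_nN,
               flagged=fit.flagged, flag_reason=fit.flag_reason)
    return row


def analyze_batch(batch: CurveBatch, options: FitOptions | None = None) -> pd.DataFrame:
    """Per-curve analysis of a whole sample batch, keeping the hierarchy labels."""
    rows = []
    for rec in batch.records:
        row = analyze_curve(rec.curve, options)
        row.update(sample=batch.sample, region=rec.region, point=rec.point,
                   replicate=rec.replicate, age=batch.age, volume=batch.volume)
        rows.append(row)
    return pd.DataFrame(rows)


METRICS = ("E_Pa", "hysteresis_ratio", "F_adh_nN")


def aggregate_hierarchy(results: pd.DataFrame,
                        metrics: tuple[str, ...] = METRICS) -> dict:
    """Collapse replicate -> point -> region -> sample -> group by successive means.

    Flagged curves are excluded and counted in the QC report; group-level SE
    uses the sample (animal) as the unit of replication and is missing for
    single-sample groups.
    """
    metrics = tuple(m for m in metrics if m in results.columns)
    qc = {
        "n_curves": int(len(results)),
        "n_flagged": int(results["flagged"].sum()),
        "flag_reasons": results.loc[results["flagged"], "flag_reason"]
                               .value_counts().to_dict(),
    }
    ok = results.loc[~results["flagged"]].copy()
    if ok.empty:
        raise ValueError("all curves flagged; nothing to aggregate")
    have_groups = ok["age"].notna().all() if "age" in ok else False

    point = (ok.groupby(["sample", "region", "point"], as_index=False)[list(metrics)]
               .mean())
    region = point.groupby(["sample", "region"], as_index=False)[list(metrics)].mean()
    sample = region.groupby(["sample"], as_index=False)[list(metrics)].mean()
    out = {"point": point, "region": region, "sample": sample, "qc": qc}
    if have_groups:
        labels = ok.groupby("sample")[["age", "volume"]].first().reset_index()
        sample = sample.merge(labels, on="sample")
        out["sample"] = sample
        grp = sample.groupby(["age", "volume"])
        rows = []
        for (age, vol), g in grp:
            row = {"age": age, "volume": vol, "n": len(g)}
            for m in metrics:
                row[f"{m}_mean"] = g[m].mean()
                row[f"{m}_se"] = (g[m].std(ddof=1) / math.sqrt(len(g))
                                  if len(g) > 1 else math.nan)
            rows.append(row)
        out["group"] = pd.DataFrame(rows)
    return out
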