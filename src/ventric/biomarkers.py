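"""Scalar electrophysiological markers and their statistical comparison.

Activation markers come from the local-activation-time (LAT) map: TAT is
the time to full depolarization (V >= 0 mV everywhere), TAT10/TAT90 the
times to activate 10%/90% of the excitable tissue volume, EDI (electrical
dyssynchrony index) the volume-weighted standard deviation of LAT, and the
apparent conduction velocity the mode of the epicardial surface CV
distribution.  Interval markers (QRS, QT) are read from the pseudo-ECG:
both end at the last return of all three limb leads to the pre-stimulus
baseline within their window.  Difference markers compare sexes on the
same geometry (QT_diff = QT_female - QT_male) and geometries for the same
sex (G-diff = detailed - smoothed); groups are compared with the
two-tailed unequal-variance (Welch) t-test.
"""

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ventric import fem
from ventric.anatomy import Mesh
from ventric.errors import AnalysisError
from ventric.monodomain import SimulationResult
from ventric.pseudo_ecg import EcgTrace


@dataclass
class BiomarkerRecord:
    """One simulated (heart, geometry, sex) cell of the experiment matrix."""

    heart: str
    geometry: str      # "detailed" | "smoothed"
    sex: str
    qrs_ms: float
    qt_ms: float
    tat_ms: float
    tat10_ms: float
    tat90_ms: float
    edi_ms: float
    cv_cm_s: float

    def as_dict(self):
        return asdict(self)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


# ---------------------------------------------------------------------------
# activation markers

def _node_volumes(mesh: Mesh) -> np.ndarray:
    return fem.lumped_mass(mesh.nodes, mesh.tets)


def activation_markers(result: SimulationResult, mesh: Mesh,
                       require_complete: bool = True):
    """(TAT, TAT10, TAT90, EDI) in ms, volume-weighted over excitable tissue.

    The activation reference is the analysis window's stimulus onset, so
    markers are invariant to a global time shift.
    """
    exc = result.excitable_mask
    lat = result.lat[exc]
    w = _node_volumes(mesh)[exc]
    act = np.isfinite(lat)
    if require_complete and not act.all():
        raise AnalysisError(
            f"incomplete activation: {int((~act).sum())} of {act.size} excitable "
            "nodes never crossed 0 mV in the analysis window")
    lat = lat[act]
    w = w[act]
    t0 = result.config.get("analysis_start_ms", 0.0)
    lat = lat - t0
    order = np.argsort(lat)
    cum = np.cumsum(w[order])
    total = cum[-1]
    tat10 = float(lat[order][np.searchsorted(cum, 0.10 * total)])
    tat90 = float(lat[order][np.searchsorted(cum, 0.90 * total)])
    tat = float(lat.max())
    mean = float(np.average(lat, weights=w))
    edi = float(np.sqrt(np.average((lat - mean) ** 2, weights=w)))
    return tat, tat10, tat90, edi


def epicardial_faces(mesh: Mesh, phi_min: float = 0.9):
    """Boundary faces whose nodes all lie on the epicardial surface."""
    faces = mesh.boundary_faces()
    return faces[(mesh.phi[faces] >= phi_min).all(axis=1)]


def apparent_cv(result: SimulationResult, mesh: Mesh,
                faces: np.ndarray | None = None, bin_cm_s: float = 2.0,
                cv_max: float = 400.0) -> float:
    """Mode of the epicardial surface conduction-velocity distribution (cm/s).

    Per-face CV is the inverse norm of the in-plane LAT gradient; the
    marker is the center of the most populated, face-area-weighted
    histogram bin (ties break toward the lower bin).  Flat-LAT faces are
    excluded; more than half excluded is an error.
    """
    if faces is None:
        faces = epicardial_faces(mesh)
    if faces.size == 0:
        raise AnalysisError("no epicardial faces available")
    lat = result.lat
    ok = np.isfinite(lat[faces]).all(axis=1)
    faces = faces[ok]
    p0, p1, p2 = (mesh.nodes[faces[:, i]] for i in range(3))
    l0, l1, l2 = (lat[faces[:, i]] for i in range(3))
    e1 = p1 - p0
    e2 = p2 - p0
    # solve for the in-plane gradient g with g.e1 = dl1, g.e2 = dl2
    a11 = np.einsum("ij,ij->i", e1, e1)
    a12 = np.einsum("ij,ij->i", e1, e2)
    a22 = np.einsum("ij,ij->i", e2, e2)
    det = a11 * a22 - a12 ** 2
    area = 0.5 * np.sqrt(np.maximum(det, 0.0))
    b1 = l1 - l0
    b2 = l2 - l0
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = (a22 * b1 - a12 * b2) / det
        c2 = (a11 * b2 - a12 * b1) / det
    g = c1[:, None] * e1 + c2[:, None] * e2
    gnorm = np.linalg.norm(g, axis=1)  # ms/cm
    with np.errstate(divide="ignore"):
        cv = 1000.0 / gnorm  # cm/s
    valid = np.isfinite(cv) & (cv <= cv_max) & (area > 0)
    if valid.sum() < 0.5 * max(1, faces.shape[0]):
        raise AnalysisError("more than half of the epicardial faces have a "
                            "flat or unusable activation gradient")
    cv = cv[valid]
    area = area[valid]
    bins = np.arange(0.0, cv_max + bin_cm_s, bin_cm_s)
    hist, edges = np.histogram(cv, bins=bins, weights=area)
    imax = int(np.argmax(hist))  # argmax takes the first (lower) bin on ties
    return float(0.5 * (edges[imax] + edges[imax + 1]))


# ---------------------------------------------------------------------------
# interval markers

def _baseline_and_band(ecg: EcgTrace, onset_ms: float, band_frac: float):
    leads = [ecg.li, ecg.lii, ecg.liii]
    pre = ecg.t < onset_ms
    base, band = [], []
    for y in leads:
        b = float(y[pre].mean()) if pre.any() else float(y[0])
        ptp = float(np.ptp(y))
        base.append(b)
        band.append(band_frac * ptp)
    return leads, base, band


def _last_baseline_return(ecg: EcgTrace, onset_ms: float, window_ms: float,
                          band_frac: float) -> float:
    """Time after onset at which all three leads have settled at baseline."""
    leads, base, band = _baseline_and_band(ecg, onset_ms, band_frac)
    sel = (ecg.t >= onset_ms) & (ecg.t <= onset_ms + window_ms)
    if not sel.any():
        raise AnalysisError("analysis window contains no samples")
    t = ecg.t[sel]
    out = np.zeros(t.size, dtype=bool)
    for y, b, d in zip(leads, base, band):
        out |= np.abs(y[sel] - b) > d
    if not out.any():
        raise AnalysisError("leads never left baseline: no complex in window")
    last_out = np.flatnonzero(out)[-1]
    if last_out == t.size - 1:
        raise AnalysisError("leads do not return to baseline within the window")
    return float(t[last_out + 1] - onset_ms)


def qrs_duration(ecg: EcgTrace, stim_onset_ms: float, window_ms: float = 200.0,
                 band_frac: float = 0.02, hold_ms: float = 10.0) -> float:
    """QRS duration: onset to the end of the depolarization complex.

    The complex ends at the last baseline crossing after which all three
    limb leads stay inside the baseline band for at least ``hold_ms`` —
    i.e. the first sustained return to baseline, so T-wave excursions
    later in the window do not extend the QRS.
    """
    leads, base, band = _baseline_and_band(ecg, stim_onset_ms, band_frac)
    sel = (ecg.t >= stim_onset_ms) & (ecg.t <= stim_onset_ms + window_ms)
    if not sel.any():
        raise AnalysisError("analysis window contains no samples")
    t = ecg.t[sel]
    out = np.zeros(t.size, dtype=bool)
    for y, b, d in zip(leads, base, band):
        out |= np.abs(y[sel] - b) > d
    if not out.any():
        raise AnalysisError("leads never left baseline: no complex in window")
    first_out = np.flatnonzero(out)[0]
    i = first_out
    while i < t.size:
        if not out[i]:
            j = np.searchsorted(t, t[i] + hold_ms)
            if not out[i:min(j, t.size)].any():
                return float(t[i] - stim_onset_ms)
            i = i + 1 + int(np.flatnonzero(out[i:])[0])
        else:
            i += 1
    raise AnalysisError("leads do not return to baseline within the window")


def qt_interval(ecg: EcgTrace, stim_onset_ms: float, window_ms: float | None = None,
                band_frac: float = 0.02) -> float:
    """QT interval: onset to the last return to baseline of the full beat
    (end of the T wave)."""
    if window_ms is None:
        window_ms = float(ecg.t.max() - stim_onset_ms)
    return _last_baseline_return(ecg, stim_onset_ms, window_ms, band_frac)


def lead_zero_crossings(ecg: EcgTrace, lead: str, t0: float, t1: float,
                        band_frac: float = 0.02) -> int:
    """Number of baseline crossings of one lead inside [t0, t1].

    Samples inside the baseline band are ignored, so a fractionated
    (notched) complex counts more crossings than a smooth one.
    """
    y = ecg.lead(lead)
    pre = ecg.t < t0
    base = float(y[pre].mean()) if pre.any() else float(y[0])
    band = band_frac * float(np.ptp(y))
    sel = (ecg.t >= t0) & (ecg.t <= t1)
    d = y[sel] - base
    signs = np.sign(d[np.abs(d) > band])
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


# ---------------------------------------------------------------------------
# difference markers and statistics

def difference_markers(records) -> dict:
    """Sex- and geometry-difference tables from matched records.

    Returns ``{"sex_diff": df, "geometry_diff": df}``: per-(heart, geometry)
    female-minus-male interval differences, and per-(heart, sex)
    detailed-minus-smoothed differences with group means.  Unmatched rows
    are dropped.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sex_rows = []
    for (heart, geom), g in df.groupby(["heart", "geometry"]):
        m = g[g.sex == "male"]
        f = g[g.sex == "female"]
        if len(m) != 1 or len(f) != 1:
            continue
        sex_rows.append({
            "heart": heart, "geometry": geom,
            "qt_diff_ms": float(f.qt_ms.iloc[0] - m.qt_ms.iloc[0]),
            "qrs_diff_ms": float(f.qrs_ms.iloc[0] - m.qrs_ms.iloc[0]),
        })
    geo_rows = []
    for (heart, sex), g in df.groupby(["heart", "sex"]):
        d = g[g.geometry == "detailed"]
        s = g[g.geometry == "smoothed"]
        if len(d) != 1 or len(s) != 1:
            continue
        row = {"heart": heart, "sex": sex}
        for col, name in (("qrs_ms", "qrs"), ("cv_cm_s", "cv"), ("qt_ms", "qt"),
                          ("tat_ms", "tat"), ("tat10_ms", "tat10"),
                          ("tat90_ms", "tat90"), ("edi_ms", "edi")):
            row[f"{name}_gdiff"] = float(d[col].iloc[0] - s[col].iloc[0])
        geo_rows.append(row)
    return {"sex_diff": pd.DataFrame(sex_rows), "geometry_diff": pd.DataFrame(geo_rows)}


def welch_ttest(group_a, group_b):
    """Welch's unequal-variance t-test: (t, df, two-tailed p).

    Degenerate zero-variance groups with equal means return (0, df, 1) by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        df = float(na + nb - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    se2 = va / na + vb / nb
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = float(se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p
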