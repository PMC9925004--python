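"""Experiment drivers, reference tables and reproducibility plumbing.

``run_matrix`` executes the sinus-rhythm experiment matrix — synthetic
heart x {detailed, smoothed} x {male, female} — extracting the full
biomarker set, sex- and geometry-difference markers, pseudo-ECG RMSDs and
the Welch comparison of QT by sex, mirroring the reporting structure of
the full-scale ex-vivo cohort study that the desk-scale fixtures emulate.

``ingest_reference_tables`` loads that cohort's published result tables
(shipped as typed CSV fixtures) so aggregate quantities can be recomputed
without any simulation.
"""

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ventric import __version__, biomarkers as bm, io
from ventric.anatomy import (BiventricularConfig, Mesh, StimulusSite,
                             make_biventricular_pair, place_iars,
                             trabecular_volume_pct)
from ventric.errors import ConfigurationError
from ventric.fibers import FiberField, assign_fibers
from ventric.monodomain import DiffusionSpec, run_simulation
from ventric.pseudo_ecg import compute_pseudo_ecg, ecg_rmsd, electrode_positions

log = logging.getLogger(__name__)

_TABLE_FILES = {
    "volumes": "cohort_volumes.csv",
    "markers": "cohort_markers.csv",
    "ecg_rmsd": "cohort_ecg_rmsd.csv",
    "vt_events": "cohort_vt_events.csv",
    "geometry_diffs": "cohort_geometry_diffs.csv",
}

_MARKER_COLUMNS = {"markers": ["heart", "geometry", "sex", "qrs_ms", "qt_ms",
                               "tat_ms", "tat10_ms", "tat90_ms", "edi_ms"],
                   "volumes": ["heart", "sex", "geometry", "myocardial_volume_cm3"]}


def ingest_reference_tables(directory=None) -> dict:
    """Typed reference tables of the four-heart ex-vivo cohort.

    Returns a dict of DataFrames keyed ``volumes``, ``markers``,
    ``ecg_rmsd``, ``vt_events``, ``geometry_diffs``.  Raises a
    configuration error naming the first missing column on a schema
    mismatch.
    """
    tables = {}
    for key, fname in _TABLE_FILES.items():
        if directory is None:
            src = resources.files("ventric.data").joinpath("reference", fname)
            with resources.as_file(src) as p:
                df = pd.read_csv(p)
        else:
            df = pd.read_csv(Path(directory) / fname)
        for col in _MARKER_COLUMNS.get(key, []):
            if col not in df.columns:
                raise ConfigurationError(f"table {key!r} is missing column {col!r}")
        tables[key] = df
    return tables


def reference_aggregates(tables: dict | None = None) -> dict:
    """Aggregate quantities recomputed from the reference tables alone.

    * per-heart trabecular volume percentage from the paired myocardial
      volumes;
    * mean female-minus-male QT prolongation per geometry (printed QT_diff
      column);
    * mean detailed-minus-smoothed TAT difference;
    * per-lead mean pseudo-ECG RMSD;
    * arrhythmic-event percentages per (geometry, sex).
    """
    if tables is None:
        tables = ingest_reference_tables()
    vols = tables["volumes"].pivot_table(index="heart", columns="geometry",
                                         values="myocardial_volume_cm3")
    trab_pct = {h: round(trabecular_volume_pct(r["detailed"], r["smoothed"]), 1)
                for h, r in vols.iterrows()}

    mk = tables["markers"]
    qt_diff_mean = {g: float(df.groupby("heart").qt_diff_printed_ms.first().mean())
                    for g, df in mk.groupby("geometry")}

    gd = tables["geometry_diffs"]
    tat_gdiff_mean = float(gd.tat_gdiff_ms.mean())

    rmsd = tables["ecg_rmsd"]
    lead_means = {lead: float(rmsd[f"lead_{lead}_mv"].mean())
                  for lead in ("i", "ii", "iii")}

    ev = tables["vt_events"].groupby(["geometry", "sex"])[["events", "simulations"]].sum()
    event_pct = {f"{g}_{s}": int(round(100.0 * r.events / r.simulations))
                 for (g, s), r in ev.iterrows()}

    return {"trabecular_pct": trab_pct, "qt_diff_mean_ms": qt_diff_mean,
            "tat_gdiff_mean_ms": tat_gdiff_mean, "ecg_rmsd_mean_mv": lead_means,
            "event_pct": event_pct}


def _surface_cv(res, mesh):
    """Apparent CV on the epicardium, falling back to the whole boundary
    on fixtures without a meaningful epicardial surface."""
    from ventric.errors import AnalysisError
    try:
        return bm.apparent_cv(res, mesh)
    except AnalysisError:
        return bm.apparent_cv(res, mesh, faces=mesh.boundary_faces())


# ---------------------------------------------------------------------------
# the experiment matrix

@dataclass
class MatrixCase:
    """One cell of the experiment matrix."""

    heart: str
    geometry: str
    sex: str
    mesh: Mesh
    fibers: FiberField
    spec: DiffusionSpec
    stimuli: list
    duration_ms: float = 100.0
    dt_ms: float = 0.02
    init_beats: int = 10
    cycle_length_ms: float = 600.0


@dataclass
class RunConfig:
    """Serializable description of a synthetic-heart matrix run."""

    heart: str = "H1"
    biventricular: BiventricularConfig = field(default_factory=BiventricularConfig)
    diffusion_scale: float = 3.5
    sexes: tuple = ("male", "female")
    duration_ms: float = 100.0
    dt_ms: float = 0.02
    init_beats: int = 10
    cycle_length_ms: float = 600.0
    seed: int = 0

    def as_dict(self):
        from dataclasses import asdict
        return asdict(self)


def matrix_cases_from_config(cfg: RunConfig) -> list[MatrixCase]:
    """Expand one synthetic heart into its four matrix cells."""
    biv = BiventricularConfig(**{**cfg.biventricular.__dict__, "seed": cfg.seed})
    detailed, smoothed = make_biventricular_pair(biv)
    spec = DiffusionSpec().with_scaled(cfg.diffusion_scale)
    cases = []
    for geometry, mesh in (("detailed", detailed), ("smoothed", smoothed)):
        fib = assign_fibers(mesh)
        sites = place_iars(mesh)
        for sex in cfg.sexes:
            cases.append(MatrixCase(cfg.heart, geometry, sex, mesh, fib, spec,
                                    sites, cfg.duration_ms, cfg.dt_ms,
                                    cfg.init_beats, cfg.cycle_length_ms))
    return cases


def run_matrix(cases: list[MatrixCase], out_dir=None, seed: int = 0) -> dict:
    """Run every matrix cell and assemble the comparison report.

    A failing cell is logged and skipped; the matrix completes.  Returns
    ``records`` (biomarker table), ``traces`` (pseudo-ECGs), ``diffs``
    (sex/geometry difference tables), ``rmsd`` (detailed-vs-smoothed
    per-lead RMSDs per heart and sex) and ``welch_qt`` (QT-by-sex Welch
    test per geometry, when both sexes are present).
    """
    records, traces = [], {}
    for case in cases:
        key = (case.heart, case.geometry, case.sex)
        try:
            res = run_simulation(case.mesh, case.fibers, case.spec, case.stimuli,
                                 case.duration_ms, sex=case.sex,
                                 cycle_length_ms=case.cycle_length_ms,
                                 dt_ms=case.dt_ms, init_beats=case.init_beats)
            ecg = compute_pseudo_ecg(res, case.mesh, case.fibers, case.spec)
            onset = min(s.onset_ms for s in case.stimuli)
            tat, tat10, tat90, edi = bm.activation_markers(res, case.mesh,
                                                           require_complete=False)

            def marker(fn, *a):
                try:
                    return fn(*a)
                except Exception as err:  # undefined marker: flagged, not fatal
                    log.warning("marker %s undefined for %s: %s",
                                fn.__name__, key, err)
                    return float("nan")

            rec = bm.BiomarkerRecord(
                heart=case.heart, geometry=case.geometry, sex=case.sex,
                qrs_ms=marker(bm.qrs_duration, ecg, onset),
                qt_ms=marker(bm.qt_interval, ecg, onset),
                tat_ms=tat, tat10_ms=tat10, tat90_ms=tat90, edi_ms=edi,
                cv_cm_s=marker(_surface_cv, res, case.mesh))
            records.append(rec)
            traces[key] = ecg
        except Exception:
            log.exception("matrix cell %s failed; continuing", key)
    frame = bm.records_to_frame(records)
    diffs = bm.difference_markers(frame) if len(frame) else {}

    rmsd = {}
    for (heart, sex) in {(k[0], k[2]) for k in traces}:
        kd, ks = (heart, "detailed", sex), (heart, "smoothed", sex)
        if kd in traces and ks in traces:
            rmsd[(heart, sex)] = ecg_rmsd(traces[kd], traces[ks])

    welch = {}
    if len(frame):
        for geometry, g in frame.groupby("geometry"):
            qt_m = g[g.sex == "male"].qt_ms.values
            qt_f = g[g.sex == "female"].qt_ms.values
            if qt_m.size >= 2 and qt_f.size >= 2:
                t, df, p = bm.welch_ttest(qt_f, qt_m)
                welch[geometry] = {"t": t, "df": df, "p": p}

    report = {"records": frame, "diffs": diffs, "rmsd": rmsd, "welch_qt": welch,
              "version": __version__, "seed": seed}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "biomarkers.csv", index=False)
        for key, ecg in traces.items():
            ecg.to_frame().to_csv(out / ("ecg_%s_%s_%s.csv" % key), index=False)
        io.write_config(out / "run_config.yaml",
                        {"version": __version__, "seed": seed,
                         "cases": [{"heart": c.heart, "geometry": c.geometry,
                                    "sex": c.sex, "duration_ms": c.duration_ms,
                                    "dt_ms": c.dt_ms} for c in cases]})
    report["traces"] = traces
    return report
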