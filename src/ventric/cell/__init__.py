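"""Human ventricular myocyte electrophysiology.

The ionic model is the O'Hara–Rudy human ventricular formulation with the
later conductance recalibration of the delayed-rectifier and late-sodium
currents exposed as the ``"dutta"`` preset (the default).  Three transmural
variants (endo / mid / epi) are built in; on top of those the module layers

* **sex phenotypes** — multiplicative channel sub-unit expression factors
  for the female heart (down-regulated repolarizing potassium currents,
  up-regulated Na/Ca exchange) relative to the male baseline, read from a
  plain-text table so they can be overridden;
* an **apex-to-base IKs gradient** — g_Ks decays linearly from apex to
  base, emulating the shorter apical action potentials.

Single-cell utilities pace a myocyte to its limit cycle (convergence is
declared when the inter-beat RMSE of the intracellular calcium transient
drops below a tolerance) and measure action-potential durations.
"""

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from numba import njit

from ventric.errors import AnalysisError, ConfigurationError, ConvergenceError, NumericalError
from ventric.cell import ord_kernel as _k
from ventric.cell.ord_kernel import NS, NP, initial_state

CELL_TYPES = ("endo", "mid", "epi")
SEXES = ("male", "female")

#: conductance-recalibration preset applied on top of the baseline model
PRESETS = {
    "baseline": {},
    "dutta": {"g_Kr": 1.119, "g_Ks": 1.648, "g_K1": 1.414, "g_NaL": 2.661, "P_Ca": 1.007},
}

# mid-myocardial variant factors relative to endo (the epicardial variant
# lives inside the kernel because it also changes Ito kinetics)
_MID_FACTORS = {"g_to": 4.0, "P_Ca": 2.5, "g_Kr": 0.8, "g_K1": 1.3,
                "g_NaCa": 1.4, "g_NaK": 0.7, "j_rel": 1.7}

_MULT_NAMES = ("g_Na", "g_NaL", "g_to", "P_Ca", "g_Kr", "g_Ks", "g_K1",
               "g_NaCa", "g_NaK", "g_Kb", "j_up", "j_rel", "cmdn")


def load_sex_factors(path=None):
    """Channel sub-unit expression multipliers per sex.

    Reads the packaged table by default; pass a path to override with a
    custom phenotype table of the same shape.
    """
    if path is None:
        text = resources.files("ventric.data").joinpath("sex_phenotype.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class CellParameterSet:
    """Effective per-current multipliers for one myocyte.

    All ``g_*`` / ``P_Ca`` / ``j_*`` fields are dimensionless multipliers
    on the published maximal conductances, permeabilities and fluxes of the
    baseline male model; a field of 1.0 everywhere with ``sex="male"`` and
    ``iks_apicobasal_scale=1`` reproduces that baseline exactly.
    """

    cell_type: str = "endo"
    sex: str = "male"
    g_Na: float = 1.0
    g_NaL: float = 1.0
    g_to: float = 1.0
    P_Ca: float = 1.0
    g_Kr: float = 1.0
    g_Ks: float = 1.0
    g_K1: float = 1.0
    g_NaCa: float = 1.0
    g_NaK: float = 1.0
    g_Kb: float = 1.0
    j_up: float = 1.0
    j_rel: float = 1.0
    cmdn: float = 1.0
    iks_apicobasal_scale: float = 1.0
    C_m: float = 1.0  # uF/cm^2
    stim_amplitude: float = -80.0  # uA/uF, depolarizing negative
    stim_duration: float = 0.5  # ms

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell_type {self.cell_type!r}")
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        for name in _MULT_NAMES:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"negative conductance multiplier {name}")
        if not (0.0 < self.iks_apicobasal_scale <= 1.0):
            raise ConfigurationError("iks_apicobasal_scale must be in (0, 1]")

    def multipliers(self) -> np.ndarray:
        """Pack into the (NP,) kernel multiplier column."""
        p = np.ones(NP)
        p[_k.PGNA] = self.g_Na
        p[_k.PGNAL] = self.g_NaL
        p[_k.PGTO] = self.g_to
        p[_k.PPCA] = self.P_Ca
        p[_k.PGKR] = self.g_Kr
        p[_k.PGKS] = self.g_Ks * self.iks_apicobasal_scale
        p[_k.PGK1] = self.g_K1
        p[_k.PGNCX] = self.g_NaCa
        p[_k.PPNAK] = self.g_NaK
        p[_k.PGKB] = self.g_Kb
        p[_k.PJUP] = self.j_up
        p[_k.PJREL] = self.j_rel
        p[_k.PCMDN] = self.cmdn
        p[_k.PEPI] = 1.0 if self.cell_type == "epi" else 0.0
        return p


def make_cell_parameters(cell_type: str, sex: str, apicobasal_position: float = 0.0,
                         preset: str = "dutta", iks_base_scale: float = 0.8,
                         sex_factors: dict | None = None) -> CellParameterSet:
    """Parameters for a myocyte at a given transmural type, sex and height.

    ``apicobasal_position`` runs 0 (apex) to 1 (base); g_Ks is scaled
    linearly from 1.0 at the apex down to ``iks_base_scale`` at the base.
    Sex factors multiply every affected current; the male phenotype is the
    identity by construction.
    """
    if cell_type not in CELL_TYPES:
        raise ConfigurationError(f"unknown cell_type {cell_type!r}")
    if sex not in SEXES:
        raise ConfigurationError(f"unknown sex {sex!r}")
    if not (0.0 <= apicobasal_position <= 1.0):
        raise ConfigurationError("apicobasal_position must be in [0, 1]")
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}")

    mult = {name: 1.0 for name in _MULT_NAMES}
    if cell_type == "mid":
        for name, f in _MID_FACTORS.items():
            mult[name] *= f
    for name, f in PRESETS[preset].items():
        mult[name] *= f
    if sex_factors is None:
        sex_factors = load_sex_factors()
    for name, f in sex_factors[sex].items():
        if name not in mult:
            raise ConfigurationError(f"unknown current {name!r} in sex factor table")
        mult[name] *= float(f)

    ab = 1.0 - (1.0 - iks_base_scale) * apicobasal_position
    return CellParameterSet(cell_type=cell_type, sex=sex,
                            iks_apicobasal_scale=ab, **mult)


def ionic_rhs(state: np.ndarray, params: CellParameterSet, i_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector (units per ms).

    Evaluated as the limit of the one-step update for a vanishing step,
    which for every sub-system (exponential gate updates, explicit
    concentration and voltage updates) converges to the exact derivative.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (NS,):
        raise ConfigurationError(f"state must have shape ({NS},)")
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise NumericalError(f"non-finite state entry {STATE_NAMES[bad]!r}")
    dt = 1e-7
    S = state[:, None].copy()
    P = params.multipliers()[:, None]
    _k.step(S, P, np.array([i_stim]), np.ones(1, dtype=np.uint8), dt)
    return (S[:, 0] - state) / dt


STATE_NAMES = [
    "V", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
]

GATE_INDICES = list(range(9, 38))  # HH-style gates constrained to [0, 1]


@njit(cache=True)
def _pace_kernel(S, P, dt, n_steps, stim_amp, stim_steps, cl_steps, sample_every,
                 out_v, out_cai):
    exc = np.ones(S.shape[1], dtype=np.uint8)
    ist = np.zeros(S.shape[1])
    j = 0
    for i in range(n_steps):
        phase = i % cl_steps
        amp = stim_amp if phase < stim_steps else 0.0
        for q in range(S.shape[1]):
            ist[q] = amp
        _k.step(S, P, ist, exc, dt)
        if (i + 1) % sample_every == 0:
            for q in range(S.shape[1]):
                out_v[j, q] = S[_k.IV, q]
                out_cai[j, q] = S[_k.ICAI, q]
            j += 1
    return j


def pace(params: CellParameterSet, n_beats: int, cycle_length_ms: float = 600.0,
         dt_ms: float = 5e-3, sample_ms: float = 0.1, state: np.ndarray | None = None):
    """Pace a single myocyte for ``n_beats`` and return sampled traces.

    Returns ``(t, V, Cai, state)`` with traces sampled every ``sample_ms``
    over the whole train and the final (end-diastolic) state vector.
    """
    if cycle_length_ms <= params.stim_duration:
        raise ConfigurationError("cycle length must exceed the stimulus duration")
    S = initial_state(1) if state is None else np.asarray(state, dtype=float)[:, None].copy()
    P = params.multipliers()[:, None]
    steps_per_beat = int(round(cycle_length_ms / dt_ms))
    sample_every = max(1, int(round(sample_ms / dt_ms)))
    n_steps = steps_per_beat * n_beats
    n_samples = n_steps // sample_every
    out_v = np.empty((n_samples, 1))
    out_cai = np.empty((n_samples, 1))
    _pace_kernel(S, P, dt_ms, n_steps, params.stim_amplitude,
                 int(round(params.stim_duration / dt_ms)), steps_per_beat,
                 sample_every, out_v, out_cai)
    t = (np.arange(n_samples) + 1) * (sample_every * dt_ms)
    return t, out_v[:, 0], out_cai[:, 0], S[:, 0]


def pace_to_limit_cycle(params: CellParameterSet, cycle_length_ms: float = 600.0,
                        dt_ms: float = 5e-3, tol_mmol: float = 1e-7,
                        max_beats: int = 1000):
    """Pace until the calcium transient repeats to within ``tol_mmol``.

    After each beat the intracellular calcium trace, resampled on a fixed
    1-ms grid, is compared with the previous beat's; pacing stops when the
    root-mean-square difference drops below the tolerance.  Returns the
    end-diastolic state, the number of beats taken and the RMSE history.
    """
    if tol_mmol <= 0 and not np.isinf(tol_mmol):
        raise ConfigurationError("tol_mmol must be positive")
    S = initial_state(1)
    P = params.multipliers()[:, None]
    steps_per_beat = int(round(cycle_length_ms / dt_ms))
    sample_every = max(1, int(round(1.0 / dt_ms)))  # 1-ms calcium resampling
    n_samples = steps_per_beat // sample_every
    out_v = np.empty((n_samples, 1))
    out_cai = np.empty((n_samples, 1))
    prev = None
    history = []
    for beat in range(1, max_beats + 1):
        _pace_kernel(S, P, dt_ms, steps_per_beat, params.stim_amplitude,
                     int(round(params.stim_duration / dt_ms)), steps_per_beat,
                     sample_every, out_v, out_cai)
        cai = out_cai[:, 0].copy()
        if prev is not None:
            rmse = float(np.sqrt(np.mean((cai - prev) ** 2)))
            history.append(rmse)
            if rmse < tol_mmol:
                return S[:, 0].copy(), beat, history
        elif np.isinf(tol_mmol):
            return S[:, 0].copy(), beat, history
        prev = cai
    raise ConvergenceError(
        f"calcium transient did not converge below {tol_mmol} mmol in {max_beats} beats",
        history=history)


def apd(t_ms: np.ndarray, v_mv: np.ndarray, repolarization_fraction: float = 0.9) -> float:
    """Action-potential duration at a repolarization fraction.

    Measured from the instant of maximum upstroke velocity to the first
    recovery of the stated fraction of the AP amplitude (peak minus the
    pre-upstroke baseline).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    v_mv = np.asarray(v_mv, dtype=float)
    dv = np.diff(v_mv)
    if dv.size == 0 or np.max(dv) <= 0:
        raise AnalysisError("no upstroke found in trace")
    iup = int(np.argmax(dv))
    if v_mv[iup:].max() - v_mv[:iup + 1].min() < 1.0:
        raise AnalysisError("no upstroke found in trace")
    if repolarization_fraction == 0:
        return 0.0
    baseline = v_mv[:iup + 1].min()
    ipk = iup + int(np.argmax(v_mv[iup:]))
    amp = v_mv[ipk] - baseline
    thr = v_mv[ipk] - repolarization_fraction * amp
    below = np.flatnonzero(v_mv[ipk:] <= thr)
    if below.size == 0:
        raise AnalysisError("trace never repolarizes to the requested fraction")
    return float(t_ms[ipk + below[0]] - t_ms[iup])
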