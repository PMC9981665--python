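"""Transfer-aware transport analysis.

Diffusion coefficients come from the Einstein relation, ``D = slope/6``
of the mean-squared displacement over a stated lag window.  Because a
proton transfer changes a residue's species label mid-run, each residue's
unfolded time series is *cut* at its transfer events and only segments of
at least a minimum length enter the per-species MSD — mobility of charged
and neutral states is never mixed.

The static conductivity is the Einstein-Helfand slope of the collective
translational dipole ``M_J = sum_i q_i r_i`` (molecular charges, unfolded
centers):

    sigma(0) = slope(<dM_J^2>) / (6 V k_B T)

A transfer executed under the minimum image appears, after unfolding, as
a charge hop across a box-scale distance and produces an artificial jump
in ``M_J``.  Each event's raw jump is replaced by its physical
contribution ``dM_J = dq_j * e * r_ij`` evaluated with the minimum-image
displacement recorded in the event log; corrections accumulate as an
additive series so the raw data stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, GeometryError
from .geometry import minimum_image
from .io import Trajectory, events_to_frame
from .system import BoxSpec, TransferEvent
from .templates import ResidueDualTemplate, TransferReaction
from .units import A2_PS_TO_M2_S, CONDUCTIVITY_TO_MS_CM, DEFAULT_UNITS, UnitSystem

__all__ = [
    "SegmentSeries",
    "DipoleSeries",
    "unfold",
    "cut_segments_at_transfers",
    "msd_multi_origin",
    "diffusion",
    "collective_dipole",
    "charges_over_time",
    "transfer_correction",
    "conductivity",
    "nernst_einstein_conductivity",
    "CORRECTION_CASES",
    "enumerate_correction_cases",
]


# ---------------------------------------------------------------------------
# unfolding
# ---------------------------------------------------------------------------


def unfold(folded: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Remove periodic wraps from a (F, M, 3) folded center trajectory.

    Consecutive-frame displacements of the result equal the minimum-image
    displacements of the input, anchored at frame 0.  Frame-to-frame
    motion must stay below half a box length per component; a residue
    moving further between two frames aliases onto the wrong image and is
    reported as an error.
    """
    folded = np.asarray(folded, float)
    if folded.ndim == 2:
        folded = folded[:, None, :]
    lengths = box.array
    steps = minimum_image(np.diff(folded, axis=0), lengths)
    # minimum_image maps into [-L/2, L/2); a component pinned at -L/2 is
    # ambiguous between images => flag as aliasing.
    bad = np.nonzero(np.any(np.isclose(np.abs(steps), lengths / 2.0), axis=-1))
    if len(bad[0]):
        f, m = int(bad[0][0]), int(bad[1][0])
        raise ConsistencyError(
            f"displacement of residue {m} between frames {f} and {f+1} reaches "
            "half a box length; sampling too sparse to unfold"
        )
    out = np.empty_like(folded)
    out[0] = folded[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = folded[0] + steps
    return out


def unfold_trajectory(traj: Trajectory) -> np.ndarray:
    """Unfold a single-bead trajectory (atoms are residue centers)."""
    return unfold(traj.positions, traj.box)


# ---------------------------------------------------------------------------
# segment cutting
# ---------------------------------------------------------------------------


@dataclass
class SegmentSeries:
    """One residue's unfolded path while it held a single species label."""

    residue_id: int
    state: str
    start_time: float
    end_time: float
    times: np.ndarray
    positions: np.ndarray  # (n, 3) unfolded

    @property
    def length(self) -> float:
        return self.end_time - self.start_time


def cut_segments_at_transfers(
    times: np.ndarray,
    unfolded: np.ndarray,
    events: Iterable[TransferEvent] | pd.DataFrame,
    initial_states: Sequence[str],
    templates: Sequence[ResidueDualTemplate],
    min_length: float,
) -> list[SegmentSeries]:
    """Partition every residue's timeline at its transfer events.

    Each returned segment is labeled with the species held during it;
    segments shorter than ``min_length`` (ps) are dropped.  ``events`` may
    be TransferEvent records or an event-log DataFrame.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    times = np.asarray(times, float)
    unfolded = np.asarray(unfolded, float)
    n_res = unfolded.shape[1]
    by_state = {s: t for t in templates for s in t.state_names}

    cut_times: dict[int, list[float]] = {m: [] for m in range(n_res)}
    if len(df):
        for _, row in df.sort_values("time_ps").iterrows():
            for col in ("residue_i", "residue_j"):
                rid = int(row[col])
                if rid < 0 or rid >= n_res:
                    raise ConsistencyError(
                        f"event at t={row['time_ps']} references unknown residue {rid}"
                    )
                cut_times[rid].append(float(row["time_ps"]))

    segments: list[SegmentSeries] = []
    t0, t_end = times[0], times[-1]
    for rid in range(n_res):
        state = initial_states[rid]
        bounds = [t0] + sorted(set(cut_times[rid])) + [t_end]
        for a, b in zip(bounds[:-1], bounds[1:]):
            mask = (times >= a - 1e-9) & (times <= b + 1e-9)
            if b - a >= min_length and mask.sum() >= 2:
                segments.append(
                    SegmentSeries(
                        residue_id=rid,
                        state=state,
                        start_time=a,
                        end_time=b,
                        times=times[mask],
                        positions=unfolded[mask, rid, :],
                    )
                )
            if b < t_end:  # crossing an event: flip the species label
                state = by_state[state].other_state(state)
    return segments


# ---------------------------------------------------------------------------
# mean-squared displacement / diffusion
# ---------------------------------------------------------------------------


def msd_multi_origin(
    positions: np.ndarray, max_lag: int, origin_stride: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MSD over multiple time origins.

    ``positions`` is (F, 3) or (F, M, 3) (averaged over M).  Returns
    (lags in frames, msd, n_samples per lag).
    """
    pos = np.asarray(positions, float)
    single = pos.ndim == 2
    if single:
        pos = pos[:, None, :]
    F = pos.shape[0]
    max_lag = min(max_lag, F - 1)
    lags = np.arange(1, max_lag + 1)
    msd = np.zeros(len(lags))
    counts = np.zeros(len(lags))
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        d = d[::origin_stride]
        msd[k] = np.mean(np.sum(d * d, axis=-1))
        counts[k] = d.shape[0] * d.shape[1]
    return lags, msd, counts


def _fit_slope(x: np.ndarray, y: np.ndarray) -> float:
    A = np.vstack([x, np.ones_like(x)]).T
    slope, _ = np.linalg.lstsq(A, y, rcond=None)[0]
    return float(slope)


def diffusion(
    segments: Sequence[SegmentSeries],
    fit_window: tuple[float, float],
    combine: Mapping[str, Sequence[str]] | None = None,
    origin_stride: int = 1,
    units: UnitSystem = DEFAULT_UNITS,
) -> pd.DataFrame:
    """Per-species diffusion coefficients from segment-averaged MSDs.

    ``fit_window`` is the (t1, t2) lag range in ps for the least-squares
    slope; ``D = slope/6``.  ``combine`` adds pooled groups, e.g.
    ``{"IM1*": ("IM1H", "IM1")}`` for the template-level coefficient.
    Returns a table with columns species, n_segments, D_A2_ps, D_m2_s.
    """
    if not segments:
        raise ValueError("no segments to analyse")
    t1, t2 = fit_window
    if t2 <= t1 or t1 < 0:
        raise ValueError(f"bad fit window {fit_window}")

    groups: dict[str, list[SegmentSeries]] = {}
    for seg in segments:
        groups.setdefault(seg.state, []).append(seg)
    if combine:
        for name, states in combine.items():
            pooled = [s for s in segments if s.state in states]
            if pooled:
                groups[name] = pooled

    rows = []
    for name, segs in groups.items():
        dt = segs[0].times[1] - segs[0].times[0]
        max_lag = int(np.floor(t2 / dt))
        acc_msd = None
        acc_n = None
        for seg in segs:
            lags, msd, n = msd_multi_origin(seg.positions, max_lag, origin_stride)
            if acc_msd is None:
                acc_msd = np.zeros(max_lag)
                acc_n = np.zeros(max_lag)
            acc_msd[: len(lags)] += msd * n
            acc_n[: len(lags)] += n
        valid = acc_n > 0
        lag_times = np.arange(1, max_lag + 1) * dt
        mean_msd = np.where(valid, acc_msd, np.nan) / np.where(valid, acc_n, 1.0)
        mask = (lag_times >= t1) & (lag_times <= t2) & valid
        if mask.sum() < 2:
            raise ValueError(
                f"species {name}: fewer than two MSD points in window {fit_window}"
            )
        slope = _fit_slope(lag_times[mask], mean_msd[mask])
        D = slope / 6.0
        rows.append((name, len(segs), D, D * A2_PS_TO_M2_S))
    return pd.DataFrame(rows, columns=["species", "n_segments", "D_A2_ps", "D_m2_s"])


# ---------------------------------------------------------------------------
# collective dipole & conductivity
# ---------------------------------------------------------------------------


@dataclass
class DipoleSeries:
    """Collective translational dipole with cumulative per-event corrections.

    ``corrections`` is piecewise constant, changing only at event times;
    ``corrected = raw + corrections``.
    """

    times: np.ndarray
    raw: np.ndarray  # (F, 3) e*A
    corrections: np.ndarray  # (F, 3), cumulative

    @property
    def corrected(self) -> np.ndarray:
        return self.raw + self.corrections


def charges_over_time(
    initial_charges: Sequence[int],
    events: Iterable[TransferEvent] | pd.DataFrame,
    times: np.ndarray,
) -> np.ndarray:
    """(F, M) residue charges at every frame.

    An event's charges apply from the frame at its event time onward
    (frames and events share time stamps in engine output).
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    times = np.asarray(times, float)
    q = np.tile(np.asarray(initial_charges, float), (len(times), 1))
    for _, row in df.iterrows():
        f0 = np.searchsorted(times, row["time_ps"] - 1e-9)
        for col_r, col_b, col_a in (
            ("residue_i", "q_i_before", "q_i_after"),
            ("residue_j", "q_j_before", "q_j_after"),
        ):
            rid = int(row[col_r])
            dq = row[col_a] - row[col_b]
            q[f0:, rid] += dq
    return q


def collective_dipole(
    unfolded: np.ndarray, charges_per_frame: np.ndarray, times: np.ndarray
) -> DipoleSeries:
    """Raw M_J(t) = sum_i q_i(t) r_i(t) over unfolded residue centers."""
    unfolded = np.asarray(unfolded, float)
    q = np.asarray(charges_per_frame, float)
    if q.shape != unfolded.shape[:2]:
        raise ConsistencyError(
            f"charge array shape {q.shape} does not match trajectory {unfolded.shape[:2]}"
        )
    raw = np.einsum("fm,fmd->fd", q, unfolded)
    return DipoleSeries(
        times=np.asarray(times, float), raw=raw, corrections=np.zeros_like(raw)
    )


#: The eight admissible (q_i_b, q_j_b, q_i_a, q_j_a) charge transitions and
#: the coefficient of e*r_ij in the physical dipole jump (== dq_j).
CORRECTION_CASES: dict[tuple[int, int, int, int], int] = {
    (0, 0, +1, -1): -1,
    (0, 0, -1, +1): +1,
    (+1, -1, 0, 0): +1,
    (-1, +1, 0, 0): -1,
    (-1, 0, 0, -1): -1,
    (0, -1, -1, 0): +1,
    (+1, 0, 0, +1): +1,
    (0, +1, +1, 0): -1,
}


def event_dipole_jump(
    q_i_before: int, q_j_before: int, q_i_after: int, q_j_after: int, r_ij: np.ndarray
) -> np.ndarray:
    """Physical dM_J of one transfer evaluated with minimum-image r_ij."""
    key = (int(q_i_before), int(q_j_before), int(q_i_after), int(q_j_after))
    if key not in CORRECTION_CASES:
        raise ConsistencyError(
            f"charge transition {key} is not a single-proton transfer case"
        )
    return CORRECTION_CASES[key] * np.asarray(r_ij, float)


def enumerate_correction_cases(
    reactions: Sequence[TransferReaction],
    templates: Sequence[ResidueDualTemplate],
) -> dict[tuple[int, int, int, int], int]:
    """All charge-transition cases reachable from a reaction set.

    For each reaction the donor/acceptor pair is considered under both
    (i, j) labelings; returns case -> coefficient of e*r_ij.
    """
    by_state = {s: t for t in templates for s in t.state_names}
    cases: dict[tuple[int, int, int, int], int] = {}
    for r in reactions:
        a, b = r.reactant_pair
        # donor = reactant currently protonated
        donor, acceptor = (a, b) if by_state[a].name_protonated == a else (b, a)
        qd_b = by_state[donor].net_charge(donor)
        qa_b = by_state[acceptor].net_charge(acceptor)
        qd_a = by_state[donor].net_charge(by_state[donor].name_deprotonated)
        qa_a = by_state[acceptor].net_charge(by_state[acceptor].name_protonated)
        for key in (
            (qd_b, qa_b, qd_a, qa_a),  # i = donor, j = acceptor
            (qa_b, qd_b, qa_a, qd_a),  # i = acceptor, j = donor
        ):
            key = tuple(int(q) for q in key)  # type: ignore[assignment]
            cases[key] = key[3] - key[1]  # dq_j
    return cases


def transfer_correction(
    dipole: DipoleSeries,
    events: Iterable[TransferEvent] | pd.DataFrame,
    unfolded: np.ndarray,
) -> DipoleSeries:
    """Replace each event's box-scale raw jump by its physical dM_J.

    For an event at frame f the raw series contains the artifact term
    ``dq_i r_i(f) + dq_j r_j(f)`` in unfolded coordinates; it is removed
    and the minimum-image contribution ``dq_j * r_ij`` (event log
    geometry) added instead.  Corrections accumulate from frame f onward.
    With no events the corrected series equals the raw one exactly.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    times = dipole.times
    unfolded = np.asarray(unfolded, float)
    corrections = np.zeros_like(dipole.raw)
    for _, row in df.iterrows():
        key = (
            int(row["q_i_before"]),
            int(row["q_j_before"]),
            int(row["q_i_after"]),
            int(row["q_j_after"]),
        )
        r_ij = np.array([row["r_ij_x"], row["r_ij_y"], row["r_ij_z"]])
        physical = event_dipole_jump(*key, r_ij)
        f0 = int(np.searchsorted(times, row["time_ps"] - 1e-9))
        if f0 >= len(times):
            raise ConsistencyError(
                f"event at t={row['time_ps']} lies outside the dipole series"
            )
        ri = unfolded[f0, int(row["residue_i"])]
        rj = unfolded[f0, int(row["residue_j"])]
        dq_i = key[2] - key[0]
        dq_j = key[3] - key[1]
        raw_jump = dq_i * ri + dq_j * rj
        corrections[f0:] += physical - raw_jump
    return DipoleSeries(times=times, raw=dipole.raw.copy(), corrections=corrections)


def conductivity(
    dipole: DipoleSeries,
    volume: float,
    temperature: float,
    fit_window: tuple[float, float],
    use: str = "corrected",
    origin_stride: int = 1,
    units: UnitSystem = DEFAULT_UNITS,
) -> dict[str, float]:
    """Static conductivity from the dipole mean-squared displacement.

    Returns sigma in internal units (e^2 / (A kcal/mol ps)) and in mS/cm,
    plus the fitted slope.  A neutral (all-zero dipole) system returns 0.
    """
    series = dipole.corrected if use == "corrected" else dipole.raw
    t1, t2 = fit_window
    dt = dipole.times[1] - dipole.times[0]
    max_lag = int(np.floor(t2 / dt))
    if max_lag < 2:
        raise ValueError("fit window shorter than two frame intervals")
    lags, msd, _ = msd_multi_origin(series, max_lag, origin_stride)
    lag_times = lags * dt
    mask = (lag_times >= t1) & (lag_times <= t2)
    if mask.sum() < 2:
        raise ValueError(f"fewer than two MSD points in window {fit_window}")
    if not np.any(np.abs(series) > 0):
        import warnings

        warnings.warn("dipole series identically zero (neutral system); sigma = 0")
        return {"sigma_internal": 0.0, "sigma_mS_cm": 0.0, "slope": 0.0}
    slope = _fit_slope(lag_times[mask], msd[mask])
    kT = units.kT(temperature)
    sigma = slope / (6.0 * volume * kT)
    return {
        "sigma_internal": sigma,
        "sigma_mS_cm": sigma * CONDUCTIVITY_TO_MS_CM,
        "slope": slope,
    }


def nernst_einstein_conductivity(
    charges: Sequence[float],
    diffusion_coefficients: Sequence[float],
    volume: float,
    temperature: float,
    units: UnitSystem = DEFAULT_UNITS,
) -> dict[str, float]:
    """Ideal (uncorrelated-ion) conductivity sum q_i^2 D_i / (V k_B T)."""
    q = np.asarray(charges, float)
    D = np.asarray(diffusion_coefficients, float)
    sigma = float(np.sum(q * q * D) / (volume * units.kT(temperature)))
    return {"sigma_internal": sigma, "sigma_mS_cm": sigma * CONDUCTIVITY_TO_MS_CM}
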