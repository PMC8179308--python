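"""Detection, classification and statistics of interlayer transport events.

Waters (and octanols) change region over time; each persistent region
change is a transition.  Water transfers between Layer-1 and Layer-2 are
classified by the hydrogen-bonded carrier cluster at the crossing:

* diffusion — the water crosses with no octanol in its carrier cluster at
  any frame of the migration window;
* stochastic flip — the carrier holds exactly one octanol and that octanol
  itself changes layer;
* hinge — the carrier holds two or more octanols (an intact
  (oct)_n(H2O)_m assembly swinging between layers).

Arrhenius activation energies follow E_a = R·T·ln(A/k) with bespoke
pre-exponential conventions (hydrogen-bond formation or surface-adsorption
rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Frame, OCTANOL, WATER
from .hbond import MoleculeCluster, find_clusters
from .layers import BULK_OCTANOL, BULK_WATER, LAYER1, LAYER2, LayerAssignment, WATER_SURFACE

R_KCAL = 1.98720425864083e-3  # gas constant, kcal mol^-1 K^-1

DIFFUSION = "diffusion"
FLIP = "flip"
HINGE = "hinge"

_DIRECTION_NAMES = {
    (LAYER1, LAYER2): "L1→L2",
    (LAYER2, LAYER1): "L2→L1",
    (LAYER2, BULK_OCTANOL): "L2→bulk",
    (BULK_OCTANOL, LAYER2): "bulk→L2",
    (BULK_WATER, WATER_SURFACE): "bulkW→surface",
}


@dataclass
class Transition:
    molecule_id: int
    from_region: str
    to_region: str
    frame_index: int  # first frame of the new region
    time: float

    @property
    def direction(self) -> str:
        return _DIRECTION_NAMES.get(
            (self.from_region, self.to_region),
            f"{self.from_region}→{self.to_region}",
        )


@dataclass
class TransportEvent:
    water_ids: frozenset[int]
    direction: str
    t_start: float
    t_end: float
    carrier: MoleculeCluster
    mechanism: str

    @property
    def n_octanol(self) -> int:
        return self.carrier.composition[0]

    @property
    def m_water(self) -> int:
        return self.carrier.composition[1]


@dataclass
class FlipEvent:
    octanol_id: int
    direction: str
    time: float
    water_hb_count: int


def detect_transitions(
    assignments: list[LayerAssignment],
    persistence: int = 1,
    molecule_ids=None,
) -> list[Transition]:
    """Persistent region changes per molecule across consecutive frames.

    A run of identical labels shorter than ``persistence`` frames is
    discarded (debounce); transitions join the surviving runs and are
    stamped at the first frame of the new region.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two assigned frames")
    mol_ids = (
        list(assignments[0].regions) if molecule_ids is None else list(molecule_ids)
    )
    times = [a.frame_time for a in assignments]
    out: list[Transition] = []
    for mid in mol_ids:
        labels = [a.regions[mid] for a in assignments]
        # run-length encode, drop short runs, merge, then read transitions
        runs: list[tuple[str, int, int]] = []  # (label, start, length)
        start = 0
        for k in range(1, len(labels) + 1):
            if k == len(labels) or labels[k] != labels[start]:
                runs.append((labels[start], start, k - start))
                start = k
        kept = [r for r in runs if r[2] >= persistence]
        merged: list[tuple[str, int, int]] = []
        for r in kept:
            if merged and merged[-1][0] == r[0]:
                last = merged[-1]
                merged[-1] = (last[0], last[1], r[1] + r[2] - last[1])
            else:
                merged.append(r)
        for prev, cur in zip(merged, merged[1:]):
            idx = cur[1]
            out.append(Transition(mid, prev[0], cur[0], idx, times[idx]))
    out.sort(key=lambda t: (t.frame_index, t.molecule_id))
    return out


def _carrier_cluster(
    frame: Frame, water_id: int, comigrating: set[int], cutoff: float
) -> MoleculeCluster:
    """Cluster containing ``water_id`` among all octanols plus the waters
    migrating in the same window (the bulk water network is excluded so a
    surface departure is not glued to the whole aqueous phase)."""
    oct_ids = [m.id for m in frame.molecules if m.species == OCTANOL]
    pool = set(oct_ids) | comigrating | {water_id}
    for c in find_clusters(frame, pool, cutoff=cutoff):
        if water_id in c.molecule_ids:
            return c
    raise RuntimeError("water not found in its own cluster")  # pragma: no cover


def classify_transfer(
    transition: Transition,
    frames: list[Frame],
    assignments: list[LayerAssignment],
    window: int = 1,
    cutoff: float = 3.5,
    comigrating: set[int] | None = None,
) -> TransportEvent:
    """Classify one water layer transition by its carrier cluster.

    The migration window spans ``window`` frames either side of the
    crossing.  The carrier is the O-O proximity cluster containing the
    water over the octanols (plus co-migrating waters); the recorded
    composition is the maximal one seen in the window.
    """
    w = transition.molecule_id
    i0 = max(transition.frame_index - 1 - window, 0)
    i1 = min(transition.frame_index + window, len(frames) - 1)
    comig = set(comigrating or ()) | {w}

    best: MoleculeCluster | None = None
    n_oct_any = 0
    for k in range(i0, i1 + 1):
        c = _carrier_cluster(frames[k], w, comig, cutoff)
        n_oct_any = max(n_oct_any, c.composition[0])
        if best is None or (c.composition[0], c.composition[1]) > best.composition:
            best = c
    assert best is not None

    if best.composition[0] >= 2:
        mech = HINGE
    elif best.composition[0] == 1:
        (oct_id,) = [
            i
            for i in best.molecule_ids
            if frames[transition.frame_index].molecule(i).species == OCTANOL
        ]
        oct_labels = {assignments[k].regions[oct_id] for k in range(i0, i1 + 1)}
        mech = FLIP if len(oct_labels) > 1 else DIFFUSION
    else:
        mech = DIFFUSION

    return TransportEvent(
        water_ids=frozenset(
            i
            for i in best.molecule_ids
            if frames[transition.frame_index].molecule(i).species == WATER
            and i in comig
        )
        or frozenset({w}),
        direction=transition.direction,
        t_start=frames[i0].time,
        t_end=frames[i1].time,
        carrier=best,
        mechanism=mech,
    )


def classify_all_transfers(
    frames: list[Frame],
    assignments: list[LayerAssignment],
    directions=(("layer1", "layer2"), ("layer2", "layer1")),
    persistence: int = 1,
    window: int = 1,
    cutoff: float = 3.5,
) -> list[TransportEvent]:
    """Detect, classify and merge all water transfers in a trajectory.

    Co-transferred waters — same direction, overlapping windows, shared
    carrier cluster — are merged into a single event.
    """
    water_ids = [m.id for m in frames[0].molecules if m.species == WATER]
    transitions = [
        t
        for t in detect_transitions(assignments, persistence, water_ids)
        if (t.from_region, t.to_region) in {tuple(d) for d in directions}
    ]
    # group transitions by direction and overlapping frame windows
    events: list[TransportEvent] = []
    by_dir: dict[str, list[Transition]] = {}
    for t in transitions:
        by_dir.setdefault(t.direction, []).append(t)
    for _, group in sorted(by_dir.items()):
        group.sort(key=lambda t: t.frame_index)
        batches: list[list[Transition]] = []
        for t in group:
            if batches and t.frame_index - batches[-1][-1].frame_index <= window:
                batches[-1].append(t)
            else:
                batches.append([t])
        for batch in batches:
            comig = {t.molecule_id for t in batch}
            done: set[int] = set()
            for t in batch:
                if t.molecule_id in done:
                    continue
                ev = classify_transfer(
                    t, frames, assignments, window, cutoff, comigrating=comig
                )
                done |= ev.water_ids
                events.append(ev)
    events.sort(key=lambda e: (e.t_start, min(e.water_ids)))
    return events


def flip_census(
    assignments: list[LayerAssignment],
    hbgraphs,
    octanol_ids,
    persistence: int = 1,
) -> tuple[list[FlipEvent], dict[str, float]]:
    """Octanol Layer-1 ⇔ Layer-2 flips with their concurrent water-HB count.

    Returns the flip list and per-direction rates normalised to events per
    10 ps of trajectory.
    """
    transitions = [
        t
        for t in detect_transitions(assignments, persistence, octanol_ids)
        if {t.from_region, t.to_region} == {LAYER1, LAYER2}
    ]
    water_like = None
    flips = []
    for t in transitions:
        g = hbgraphs[t.frame_index]
        count = 0
        for d, a, _ in g.edges:
            if t.molecule_id in (d, a):
                other = a if d == t.molecule_id else d
                if other not in octanol_ids:
                    count += 1
        flips.append(FlipEvent(t.molecule_id, t.direction, t.time, count))
    span = assignments[-1].frame_time - assignments[0].frame_time
    rates = {}
    for direction in ("L1→L2", "L2→L1"):
        n = sum(1 for f in flips if f.direction == direction)
        rates[direction] = n / span * 10.0 if span > 0 else 0.0
    return flips, rates


# ---------------------------------------------------------------------------
# statistics


def _block_sem(values: np.ndarray, n_blocks: int = 3) -> float:
    """SEM of block means (values already in time order)."""
    values = np.asarray(values, dtype=float)
    if len(values) < n_blocks:
        return float("nan")
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / math.sqrt(n_blocks))


@dataclass
class DirectionStats:
    direction: str
    n_events: int
    waters_transferred: int
    mean_octanols: float
    mean_waters: float
    sem_octanols: float
    sem_waters: float
    mechanism_fraction_events: dict[str, float]
    mechanism_fraction_waters: dict[str, float]

    @property
    def per_water_stoichiometry(self) -> float:
        return self.mean_octanols / self.mean_waters


@dataclass
class TransferStats:
    by_direction: dict[str, DirectionStats]

    def __getitem__(self, direction: str) -> DirectionStats:
        return self.by_direction[direction]


def transfer_statistics(events: list[TransportEvent], n_blocks: int = 3) -> TransferStats:
    """Aggregate classified events per direction.

    Mechanism fractions are reported both by event count and by waters
    transferred; uncertainties use 3-block averaging over the time-ordered
    event list.  Mean octanols/waters per event are computed over
    HB-mediated events (diffusing waters carry no octanol and are excluded
    from the carrier-composition means, as they have no carrier).
    """
    by_dir: dict[str, list[TransportEvent]] = {}
    for e in sorted(events, key=lambda e: e.t_start):
        by_dir.setdefault(e.direction, []).append(e)
    out = {}
    for direction, evs in by_dir.items():
        n_events = len(evs)
        waters = np.array([len(e.water_ids) for e in evs])
        total_w = int(waters.sum())
        mech_ev = {m: 0 for m in (DIFFUSION, FLIP, HINGE)}
        mech_w = {m: 0 for m in (DIFFUSION, FLIP, HINGE)}
        for e in evs:
            mech_ev[e.mechanism] += 1
            mech_w[e.mechanism] += len(e.water_ids)
        hb_evs = [e for e in evs if e.mechanism != DIFFUSION]
        octs = np.array([e.n_octanol for e in hb_evs], dtype=float)
        hbw = np.array([len(e.water_ids) for e in hb_evs], dtype=float)
        out[direction] = DirectionStats(
            direction=direction,
            n_events=n_events,
            waters_transferred=total_w,
            mean_octanols=float(octs.mean()) if len(octs) else 0.0,
            mean_waters=float(hbw.mean()) if len(hbw) else 0.0,
            sem_octanols=_block_sem(octs, n_blocks) if len(octs) else float("nan"),
            sem_waters=_block_sem(hbw, n_blocks) if len(hbw) else float("nan"),
            mechanism_fraction_events={
                m: (c / n_events if n_events else 0.0) for m, c in mech_ev.items()
            },
            mechanism_fraction_waters={
                m: (c / total_w if total_w else 0.0) for m, c in mech_w.items()
            },
        )
    return TransferStats(out)


def diffusion_share(n_diffusion_waters: int, n_hb_waters: int) -> float:
    """Fraction (%) of transferred waters that crossed by bare diffusion."""
    total = n_diffusion_waters + n_hb_waters
    if total == 0:
        raise ValueError("no transferred waters")
    return 100.0 * n_diffusion_waters / total


def per_water_stoichiometry(mean_octanols: float, mean_waters: float) -> float:
    """Octanols engaged per transferred water, n_oct / m_water."""
    if mean_waters <= 0:
        raise ValueError("mean_waters must be positive")
    return mean_octanols / mean_waters


# ---------------------------------------------------------------------------
# Arrhenius


@dataclass
class ArrheniusEstimate:
    k: float
    A: float
    T: float
    E_a: float  # kcal/mol
    negative_flagged: bool = False
    sem: float = float("nan")


def arrhenius_ea(k: float, A: float, T: float) -> ArrheniusEstimate:
    """Activation energy from rate constant and prefactor, E_a = R·T·ln(A/k).

    A negative result (A < k) is flagged rather than clipped.
    """
    if k <= 0 or A <= 0 or T <= 0:
        raise ValueError("k, A and T must all be positive")
    ea = R_KCAL * T * math.log(A / k)
    return ArrheniusEstimate(k=k, A=A, T=T, E_a=ea, negative_flagged=ea < 0)


def hinge_reaction_rates(
    events: list[TransportEvent],
    duration: float,
    concentrations: dict[str, float],
    A_fwd: float,
    A_rev: float,
    T: float = 300.0,
    stoichiometry: float = 1.63,
    n_blocks: int = 3,
) -> tuple[ArrheniusEstimate, ArrheniusEstimate]:
    """Forward/reverse activation energies for the per-water hinge reaction
    H2O(L1) + s·oct(L1) ⇔ H2O(L2) + s·oct(L2).

    The rate constant in each direction is the water-transfer rate divided
    by [H2O]·[oct]^s of the source layer; ``concentrations`` must contain
    ``water_L1``, ``oct_L1``, ``water_L2``, ``oct_L2`` (any consistent
    units — the convention is recorded on the estimate through k itself).
    The prefactors are supplied by the caller (HB-formation-rate or
    surface-adsorption convention).  SEMs come from 3-block averaging of
    the per-block transfer rates.
    """
    for key in ("water_L1", "oct_L1", "water_L2", "oct_L2"):
        if concentrations.get(key, 0.0) <= 0:
            raise ValueError(f"concentration {key} must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t0 = min((e.t_start for e in events), default=0.0)

    def direction_rate(direction: str):
        evs = sorted(
            (e for e in events if e.direction == direction), key=lambda e: e.t_start
        )
        waters = sum(len(e.water_ids) for e in evs)
        rate = waters / duration
        # block rates over thirds of the time span
        edges = np.linspace(0.0, duration, n_blocks + 1)
        block_rates = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            w = sum(
                len(e.water_ids) for e in evs if lo <= e.t_start - t0 < hi
            ) if evs else 0
            block_rates.append(w / (hi - lo))
        return rate, np.array(block_rates)

    out = []
    for direction, A, src in (("L1→L2", A_fwd, "L1"), ("L2→L1", A_rev, "L2")):
        rate, block_rates = direction_rate(direction)
        denom = (
            concentrations[f"water_{src}"]
            * concentrations[f"oct_{src}"] ** stoichiometry
        )
        if rate <= 0:
            raise ValueError(f"no {direction} events; rate is zero")
        k = rate / denom
        est = arrhenius_ea(k, A, T)
        with np.errstate(divide="ignore"):
            block_eas = [
                R_KCAL * T * math.log(A / (r / denom)) for r in block_rates if r > 0
            ]
        if len(block_eas) == n_blocks:
            est.sem = float(np.std(block_eas, ddof=1) / math.sqrt(n_blocks))
        out.append(est)
    return out[0], out[1]
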