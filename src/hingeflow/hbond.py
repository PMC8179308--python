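"""Per-frame hydrogen-bond graphs and hydrogen-bonded molecule clusters.

A hydrogen bond between two molecules (water-water, water-octanol or
octanol-octanol alike) is purely geometric: the donor and acceptor oxygens
are closer than ``max_OO_distance`` (minimum image) and the H-O(donor)...O
(acceptor) angle at the donor oxygen is at most ``max_HOO_angle``.  Molecule
clusters use the simpler O-O proximity criterion at the same 3.5 Å scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import Box, Frame, Trajectory, OCTANOL, WATER, minimum_image

DEFAULT_OO_CUTOFF = 3.5  # Å
DEFAULT_HOO_ANGLE = 30.0  # degrees


@dataclass(frozen=True)
class HBCriteria:
    max_OO_distance: float = DEFAULT_OO_CUTOFF
    max_HOO_angle: float = DEFAULT_HOO_ANGLE

    def __post_init__(self) -> None:
        if self.max_OO_distance <= 0:
            raise ValueError("max_OO_distance must be positive")
        if not 0 < self.max_HOO_angle <= 180:
            raise ValueError("max_HOO_angle must be in (0, 180]")


@dataclass
class HBGraph:
    """Directed hydrogen-bond graph of one frame.

    Edges are (donor molecule id, acceptor molecule id, donor H atom id).
    """

    frame_time: float
    nodes: frozenset[int]
    edges: frozenset[tuple[int, int, int]]
    # parallel per-edge geometry, keyed by edge tuple
    geometry: dict[tuple[int, int, int], tuple[float, float]] = field(
        default_factory=dict
    )

    def undirected_pairs(self) -> frozenset[frozenset[int]]:
        return frozenset(frozenset((d, a)) for d, a, _ in self.edges)

    def neighbors(self, mol_id: int) -> set[int]:
        out = set()
        for d, a, _ in self.edges:
            if d == mol_id:
                out.add(a)
            elif a == mol_id:
                out.add(d)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((d, a) for d, a, _ in self.edges)
        return g


@dataclass
class MoleculeCluster:
    molecule_ids: frozenset[int]
    composition: tuple[int, int]  # (n_octanol, m_water)
    frame_time: float

    def __len__(self) -> int:
        return len(self.molecule_ids)


def _pbc_tree(points: np.ndarray, box: Box) -> cKDTree:
    """KD-tree honouring the box's per-axis periodicity.

    Non-periodic axes get a boxsize twice the cell length so the wrap can
    never connect points across that face (inputs must be wrapped).
    """
    L = box.lengths
    boxsize = np.where(box.periodic_mask, L, 2.0 * L)
    return cKDTree(np.mod(points, boxsize), boxsize=boxsize)


def detect_hbonds(frame: Frame, criteria: HBCriteria | None = None) -> HBGraph:
    """Build the directed hydrogen-bond graph of a wrapped frame.

    A neighbour search over donor/acceptor oxygens prunes candidate pairs;
    the final test uses exact minimum-image geometry, so results are
    identical to an all-pairs scan.
    """
    criteria = criteria or HBCriteria()
    mols = frame.molecules
    ids = []
    o_pos = []
    for m in mols:
        try:
            o = m.key_oxygen
        except KeyError:
            raise ValueError(f"molecule {m.id} lacks an O role") from None
        ids.append(m.id)
        o_pos.append(o.position)
    ids = np.array(ids, dtype=int)
    o_pos = np.asarray(o_pos, dtype=float)

    edges: set[tuple[int, int, int]] = set()
    geometry: dict[tuple[int, int, int], tuple[float, float]] = {}
    if len(ids) >= 2:
        tree = _pbc_tree(o_pos, frame.box)
        pairs = tree.query_pairs(criteria.max_OO_distance, output_type="ndarray")
        cos_min = np.cos(np.deg2rad(criteria.max_HOO_angle))
        for i, j in pairs:
            d_oo = minimum_image(o_pos[i], o_pos[j], frame.box)
            r = float(np.linalg.norm(d_oo))
            if not r < criteria.max_OO_distance:
                continue  # tree cutoff is inclusive; criterion is strict
            for di, ai, v_oo in ((i, j, d_oo), (j, i, -d_oo)):
                donor = mols[di]
                for h in donor.donor_hydrogens:
                    v_oh = minimum_image(o_pos[di], h.position, frame.box)
                    nh = float(np.linalg.norm(v_oh))
                    if nh == 0.0:
                        continue
                    cos_a = float(np.dot(v_oh, v_oo) / (nh * r))
                    if cos_a >= cos_min - 1e-12:
                        ang = float(np.degrees(np.arccos(np.clip(cos_a, -1, 1))))
                        if ang <= criteria.max_HOO_angle:
                            edge = (int(ids[di]), int(ids[ai]), int(h.id))
                            edges.add(edge)
                            geometry[edge] = (r, ang)
    return HBGraph(
        frame_time=frame.time,
        nodes=frozenset(int(i) for i in ids),
        edges=frozenset(edges),
        geometry=geometry,
    )


def find_clusters(
    frame: Frame,
    member_ids,
    cutoff: float = DEFAULT_OO_CUTOFF,
) -> list[MoleculeCluster]:
    """Connected components of the O-O proximity graph over ``member_ids``.

    Two molecules join the same cluster iff their key oxygens are closer
    than ``cutoff`` (transitively).  Clusters are ordered by their smallest
    member id.
    """
    member_ids = list(member_ids)
    if not member_ids:
        return []
    ids, o_pos = frame.key_oxygens(member_ids)
    n = len(ids)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        tree = _pbc_tree(o_pos, frame.box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        keep = []
        for i, j in pairs:
            d = minimum_image(o_pos[i], o_pos[j], frame.box)
            if np.linalg.norm(d) < cutoff:
                keep.append((i, j))
        if keep:
            keep = np.array(keep)
            adj = coo_matrix(
                (np.ones(len(keep)), (keep[:, 0], keep[:, 1])), shape=(n, n)
            )
            _, labels = connected_components(adj, directed=False)
        else:
            labels = np.arange(n)

    species = {m.id: m.species for m in frame.molecules}
    groups: dict[int, list[int]] = {}
    for mol_id, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(int(mol_id))
    clusters = []
    for members in groups.values():
        n_oct = sum(1 for i in members if species[i] == OCTANOL)
        m_wat = sum(1 for i in members if species[i] == WATER)
        clusters.append(
            MoleculeCluster(
                molecule_ids=frozenset(members),
                composition=(n_oct, m_wat),
                frame_time=frame.time,
            )
        )
    clusters.sort(key=lambda c: min(c.molecule_ids))
    return clusters


def hb_turnover_rates(
    trajectory: Trajectory,
    fine_interval: float | None = None,
    criteria: HBCriteria | None = None,
    graphs: list[HBGraph] | None = None,
    subset=None,
) -> tuple[float, float]:
    """Hydrogen-bond (formation, loss) rates per 10 ps.

    Counts undirected molecular HB pairs appearing (formation) or vanishing
    (loss) between consecutive frames, normalised to events per 10 ps.  With
    ``subset`` given, only pairs touching at least one subset molecule count
    (e.g. the octanols of one layer).
    """
    if len(trajectory) < 2:
        raise ValueError("turnover rates need at least two frames")
    dt = fine_interval if fine_interval is not None else trajectory.sampling_interval
    if graphs is None:
        graphs = [detect_hbonds(f, criteria) for f in trajectory]
    subset = None if subset is None else set(subset)

    def pairs_of(g: HBGraph):
        p = g.undirected_pairs()
        if subset is not None:
            p = frozenset(q for q in p if q & subset)
        return p

    formed = lost = 0
    prev = pairs_of(graphs[0])
    for g in graphs[1:]:
        cur = pairs_of(g)
        formed += len(cur - prev)
        lost += len(prev - cur)
        prev = cur
    span = dt * (len(graphs) - 1)
    scale = 10.0 / span
    return formed * scale, lost * scale
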