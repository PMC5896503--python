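"""Coccosphere topology via Euler's polyhedron formula.

A complete coccosphere is topologically a convex polyhedron whose faces
are coccoliths: every two neighbouring coccoliths overlap along an edge
and every three overlaps meet at a junction, so the polyhedron is cubic
(trivalent).  With face sizes restricted to 4–6 neighbours per
coccolith, Euler's formula ``F + V − E = 2`` reduces to the face-vector
constraint

    Σ (6 − n) F_n = 12   ⇔   2·F₄ + F₅ = 12,

which this module enumerates, and whose solutions it tests for
geometric existence by exhaustive, isomorph-free generation of the
3-connected cubic planar graphs with the requested face-size multiset.

Generation uses the classical edge-insertion construction: every
3-connected cubic planar graph arises from the tetrahedron K₄ by
repeatedly subdividing two distinct edges of a face and joining the two
new vertices.  Graphs are stored as planar rotation systems (clockwise
neighbour lists) and deduplicated with a planar-code canonical form
minimised over all starting directed edges and both orientations, so
mirror images are identified.  Face sizes of intermediate graphs are
unrestricted — a face larger than six can later be split — which is why
the construction is exhaustive per face count rather than pruned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "FaceComposition",
    "PolyhedronGraph",
    "CompositionCatalog",
    "CatalogEntry",
    "EulerReport",
    "NotTestedError",
    "DEFAULT_TRACTABLE_FACES",
    "enumerate_compositions",
    "mean_edges_per_face",
    "generate_polyhedra",
    "cubic_planar_graphs",
    "minimal_coccosphere_size",
    "check_euler",
]

#: Largest face count for which exhaustive generation runs by default.
#: V = 2(f − 2) vertices; beyond this the catalog reports "not tested".
DEFAULT_TRACTABLE_FACES = 12

Rotation = tuple[tuple[int, ...], ...]


class NotTestedError(RuntimeError):
    """Raised when exhaustive generation is requested beyond the tractable bound."""


@dataclass(frozen=True, order=True)
class FaceComposition:
    """Counts (F₄, F₅, F₆) of 4-, 5- and 6-edged coccoliths on one coccosphere."""

    f4: int
    f5: int
    f6: int

    def __post_init__(self) -> None:
        if min(self.f4, self.f5, self.f6) < 0:
            raise ValueError("face counts must be nonnegative")
        if 2 * self.f4 + self.f5 != 12:
            raise ValueError(
                f"composition ({self.f4}, {self.f5}, {self.f6}) violates 2·F4 + F5 = 12"
            )

    @property
    def f(self) -> int:
        """Total number of faces (coccoliths)."""
        return self.f4 + self.f5 + self.f6

    @property
    def face_size_multiset(self) -> tuple[int, ...]:
        return (4,) * self.f4 + (5,) * self.f5 + (6,) * self.f6


# ---------------------------------------------------------------------------
# rotation-system primitives


def _trace_faces(rot: Rotation) -> list[list[int]]:
    """Partition the directed edges of a rotation system into face cycles.

    Faces are traced with the rule next(u→v) = v→(successor of u in the
    rotation at v); each face is returned as its cyclic vertex sequence.
    Raises ``ValueError`` naming the offending face walk if the adjacency
    lists are inconsistent.
    """
    seen: set[tuple[int, int]] = set()
    faces: list[list[int]] = []
    for u0 in range(len(rot)):
        for v0 in rot[u0]:
            if (u0, v0) in seen:
                continue
            face = []
            u, v = u0, v0
            while (u, v) not in seen:
                seen.add((u, v))
                face.append(u)
                try:
                    i = rot[v].index(u)
                except ValueError:
                    raise ValueError(
                        f"malformed embedding: face walk {face + [v]} uses edge "
                        f"({u}, {v}) but {u} is not in the rotation of {v}"
                    ) from None
                u, v = v, rot[v][(i + 1) % len(rot[v])]
            if (u, v) != (u0, v0):
                raise ValueError(f"malformed embedding: face walk starting at ({u0}, {v0}) does not close")
            faces.append(face)
    return faces


def _walk_code(
    rot: Rotation, u: int, v: int, mirror: bool, best: Optional[tuple[int, ...]] = None
) -> Optional[tuple[int, ...]]:
    """Planar (BFS) code of the embedding rooted at directed edge u→v.

    Vertices are labelled in discovery order; each vertex contributes the
    labels of its neighbours in rotation order (reversed if ``mirror``)
    starting from the discovering neighbour, followed by a separator.
    When ``best`` is given, the walk aborts and returns ``None`` as soon
    as its code is lexicographically larger than ``best``.
    """
    n = len(rot)
    labels = [-1] * n
    labels[u] = 0
    order = [u]
    first = [0] * n
    first[u] = v
    code: list[int] = []
    append = code.append
    comparing = best is not None
    pos = 0
    for w in order:
        nbrs = rot[w]
        deg = len(nbrs)
        i = nbrs.index(first[w])
        if mirror:
            seq = tuple(nbrs[(i - k) % deg] for k in range(deg))
        else:
            seq = tuple(nbrs[(i + k) % deg] for k in range(deg))
        for x in seq:
            lab = labels[x]
            if lab == -1:
                lab = len(order)
                labels[x] = lab
                order.append(x)
                first[x] = w
            append(lab)
            if comparing:
                b = best[pos]
                if lab > b:
                    return None
                if lab < b:
                    comparing = False
            pos += 1
        append(-1)
        if comparing:
            b = best[pos]
            if -1 > b:  # pragma: no cover - separators align for regular graphs
                return None
            if -1 < b:
                comparing = False
        pos += 1
    return tuple(code)


def _canonical_code(rot: Rotation) -> tuple[int, ...]:
    """Canonical form: minimum walk code over all roots and both orientations."""
    best: Optional[tuple[int, ...]] = None
    for u in range(len(rot)):
        for v in rot[u]:
            for mirror in (False, True):
                code = _walk_code(rot, u, v, mirror, best)
                if code is not None and (best is None or code < best):
                    best = code
    assert best is not None
    return best


def _insert_edge(rot: Rotation, face_edges: list[tuple[int, int]], i: int, j: int) -> Rotation:
    """Subdivide face edges i and j and join the two new vertices.

    ``face_edges`` is the directed boundary walk of one face (interior on
    the traced side).  Returns a new rotation system with two extra
    vertices; the operation keeps the graph simple, cubic, planar and
    3-connected.
    """
    a, b = face_edges[i]
    c, d = face_edges[j]
    x = len(rot)
    y = x + 1
    new = [list(r) for r in rot]

    def _replace(vertex: int, old: int, newv: int) -> None:
        new[vertex][new[vertex].index(old)] = newv

    _replace(a, b, x)
    _replace(b, a, x)
    _replace(c, d, y)
    _replace(d, c, y)
    # x sits on a→b with the face interior to the traced side; y likewise on
    # c→d.  Neighbour order chosen so the face splits into two faces.
    new.append([a, y, b])
    new.append([c, x, d])
    return tuple(tuple(r) for r in new)


# K4 with a planar rotation system (verified: four triangular faces).
_K4: Rotation = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))

_levels: dict[int, list[Rotation]] = {}


def _face_edge_lists(rot: Rotation) -> list[list[tuple[int, int]]]:
    faces = _trace_faces(rot)
    return [[(f[k], f[(k + 1) % len(f)]) for k in range(len(f))] for f in faces]


def _extend_levels(f_target: int) -> None:
    """Grow the per-face-count catalogue of cubic planar graphs up to f_target."""
    if not _levels:
        _levels[4] = [_K4]
    f_have = max(_levels)
    while f_have < f_target:
        children: dict[tuple[int, ...], Rotation] = {}
        for rot in _levels[f_have]:
            for face in _face_edge_lists(rot):
                k = len(face)
                for i in range(k):
                    for j in range(i + 1, k):
                        # the two subdivided edges must be distinct edges
                        if frozenset(face[i]) == frozenset(face[j]):
                            continue
                        child = _insert_edge(rot, face, i, j)
                        code = _canonical_code(child)
                        if code not in children:
                            children[code] = child
        f_have += 1
        _levels[f_have] = list(children.values())


def cubic_planar_graphs(f: int) -> list["PolyhedronGraph"]:
    """All 3-connected cubic planar graphs with ``f`` faces, up to isomorphism.

    Exhaustive and isomorph-free (mirror images identified); no face-size
    restriction.  Intended for small ``f`` — the count grows as fast as
    the number of planar triangulations on ``f`` vertices.
    """
    if f < 4:
        return []
    _extend_levels(f)
    return [PolyhedronGraph(rot) for rot in _levels[f]]


@dataclass(frozen=True)
class PolyhedronGraph:
    """A cubic planar graph with its embedding (rotation system).

    ``rotation[v]`` lists the neighbours of vertex ``v`` in cyclic order;
    faces are recovered by face tracing and correspond to coccoliths.
    """

    rotation: Rotation

    @property
    def n_vertices(self) -> int:
        return len(self.rotation)

    @property
    def edges(self) -> list[tuple[int, int]]:
        out = {tuple(sorted((u, v))) for u in range(len(self.rotation)) for v in self.rotation[u]}
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def faces(self) -> list[list[int]]:
        return _trace_faces(self.rotation)

    @property
    def face_sizes(self) -> tuple[int, ...]:
        return tuple(sorted(len(f) for f in self.faces))

    @property
    def composition(self) -> Optional[FaceComposition]:
        """The (F₄, F₅, F₆) composition, or None if any face size is outside 4–6."""
        sizes = self.face_sizes
        if any(s < 4 or s > 6 for s in sizes):
            return None
        return FaceComposition(sizes.count(4), sizes.count(5), sizes.count(6))

    def planar_code(self) -> str:
        """One-line ASCII planar code: ``V | nbrs(v0) | nbrs(v1) | ...``.

        Neighbour lists are given in rotation order, vertices numbered
        from 0, so the embedding is preserved.
        """
        parts = [str(self.n_vertices)]
        parts += [" ".join(str(x) for x in nbrs) for nbrs in self.rotation]
        return " | ".join(parts)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g


@dataclass
class CatalogEntry:
    composition: FaceComposition
    status: str = "not tested"  # "realized" | "not realized" | "not tested"
    isomers: Optional[int] = None


@dataclass
class CompositionCatalog:
    """Admissible face compositions per face count, with realizability notes."""

    f_min: int
    f_max: int
    entries: dict[int, list[CatalogEntry]]

    def annotate(self, tractable_f: int = DEFAULT_TRACTABLE_FACES) -> "CompositionCatalog":
        """Mark each composition realized/not realized by exhaustive generation.

        Compositions with more than ``tractable_f`` faces keep the
        explicit "not tested" status rather than a silent empty result.
        """
        for f, group in self.entries.items():
            if f > tractable_f:
                continue
            for entry in group:
                graphs = generate_polyhedra(entry.composition, f_max=tractable_f)
                entry.isomers = len(graphs)
                entry.status = "realized" if graphs else "not realized"
        return self

    def to_records(self) -> list[dict]:
        return [
            {
                "f": f,
                "f4": e.composition.f4,
                "f5": e.composition.f5,
                "f6": e.composition.f6,
                "status": e.status,
                "isomers": e.isomers,
            }
            for f in sorted(self.entries)
            for e in self.entries[f]
        ]


def _compositions_for(f: int) -> list[FaceComposition]:
    out = []
    for f4 in range(0, 7):
        f5 = 12 - 2 * f4
        f6 = f - f4 - f5
        if f6 >= 0:
            out.append(FaceComposition(f4, f5, f6))
    return out


def enumerate_compositions(f_min: int, f_max: int) -> CompositionCatalog:
    """All integer solutions of 2F₄ + F₅ = 12 with F₄+F₅+F₆ = f, per f.

    Entries are ordered lexicographically by F₄ and carry the status
    "not tested" until :meth:`CompositionCatalog.annotate` is called.
    """
    if not (4 <= f_min <= f_max):
        raise ValueError(f"need 4 <= f_min <= f_max, got f_min={f_min}, f_max={f_max}")
    return CompositionCatalog(
        f_min, f_max, {f: [CatalogEntry(c) for c in _compositions_for(f)] for f in range(f_min, f_max + 1)}
    )


def mean_edges_per_face(f: float) -> float:
    """Mean number of edges per face of a cubic polyhedron with ``f`` faces.

    From Euler's formula, n̄ = 6 − 12/f; non-integer ``f`` is accepted so
    the identity can be applied at a population mean coccolith count.
    """
    if f <= 0:
        raise ValueError(f"face count must be positive, got {f}")
    return 6.0 - 12.0 / f


def generate_polyhedra(
    composition: FaceComposition,
    limit: Optional[int] = None,
    f_max: int = DEFAULT_TRACTABLE_FACES,
) -> list[PolyhedronGraph]:
    """Isomorph-free exhaustive list of cubic polyhedra realizing a composition.

    An empty list means the composition is *proved* unrealizable (the
    generation is exhaustive).  Compositions beyond ``f_max`` faces raise
    :class:`NotTestedError` instead of silently returning nothing.
    """
    if composition.f > f_max:
        raise NotTestedError(
            f"composition with {composition.f} faces exceeds the tractable bound f_max={f_max}; "
            "status is 'not tested', not 'not realized'"
        )
    target = tuple(sorted(composition.face_size_multiset))
    out = []
    for g in cubic_planar_graphs(composition.f):
        if g.face_sizes == target:
            out.append(g)
            if limit is not None and len(out) >= limit:
                break
    return out


def minimal_coccosphere_size(
    f_min: int = 4, f_max: int = DEFAULT_TRACTABLE_FACES
) -> Optional[int]:
    """Smallest face count with a realizable all-faces-4-to-6 composition.

    Scans face counts from ``f_min`` upward, exhaustively generating the
    cubic polyhedra at each size; returns the first ``f`` at which some
    Euler-admissible composition is realized (6: the cube), or ``None``
    if nothing is realizable up to ``f_max``.
    """
    for f in range(f_min, f_max + 1):
        for comp in _compositions_for(f):
            if generate_polyhedra(comp, limit=1, f_max=f_max):
                return f
    return None


@dataclass
class EulerReport:
    """Per-condition verdicts for a candidate coccosphere polyhedron."""

    n_faces: int
    n_vertices: int
    n_edges: int
    euler_ok: bool
    cubic_ok: bool
    face_sizes_ok: bool
    three_connected_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.euler_ok and self.cubic_ok and self.face_sizes_ok and self.three_connected_ok


def check_euler(graph: PolyhedronGraph | Rotation) -> EulerReport:
    """Verify the coccosphere polyhedron conditions on an embedded graph.

    Checks F + V − E = 2 (from the traced faces), trivalence of every
    vertex, face sizes within 4–6, and 3-connectivity (by exhaustive
    two-vertex removal).  A malformed embedding raises ``ValueError``
    naming the inconsistent face walk.
    """
    rot = graph.rotation if isinstance(graph, PolyhedronGraph) else tuple(tuple(r) for r in graph)
    faces = _trace_faces(rot)
    V = len(rot)
    E = sum(len(r) for r in rot) // 2
    F = len(faces)
    g = nx.Graph((u, v) for u in range(V) for v in rot[u])
    three_conn = V > 3 and all(
        nx.is_connected(nx.restricted_view(g, [u, v], []))
        for u in range(V)
        for v in range(u + 1, V)
    )
    return EulerReport(
        n_faces=F,
        n_vertices=V,
        n_edges=E,
        euler_ok=(F + V - E == 2),
        cubic_ok=all(len(r) == 3 for r in rot),
        face_sizes_ok=all(4 <= len(f) <= 6 for f in faces),
        three_connected_ok=three_conn,
    )
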