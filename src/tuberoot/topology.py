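"""Tree-structured plant models with child-chain (child-sibling) storage.

The tuber-root system divides into three chains sharing one tree: seed
potato -> seminal roots; seed potato -> underground stem -> creeping stems
-> tubers; underground stem -> creeping roots.  The seed potato is the root
node (level 1), the underground stem and seminal roots sit at level 2,
stem-borne creeping roots and creeping stems at level 3, and tubers — one at
the terminal node of a creeping stem — at level 4.  Each node stores a
first-child and a next-sibling reference (child-chain notation), so a plant
is traversable without any auxiliary index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .database import ParameterDatabase, ROOT_CLASSES
from .distributions import ValidationError
from .growth import RootAxis, axis_depth, generate_axis

__all__ = ["OrganNode", "PlantModel", "build_plant", "traverse"]

_LEVELS = {
    "seed_potato": 1,
    "underground_stem": 2,
    "seminal_root": 2,
    "creeping_root": 3,
    "creeping_stem": 3,
    "tuber": 4,
}


@dataclass
class OrganNode:
    """One organ instance: a node in the child-sibling tree."""

    node_id: int
    organ_class: str
    level: int
    params: dict[str, float] = field(default_factory=dict)
    parent_id: int | None = None
    distance_along_parent: float = 0.0
    axis: RootAxis | None = None
    position: np.ndarray | None = None  # attachment / center point, mm
    first_child: "OrganNode | None" = field(default=None, repr=False)
    next_sibling: "OrganNode | None" = field(default=None, repr=False)

    def children(self):
        child = self.first_child
        while child is not None:
            yield child
            child = child.next_sibling


@dataclass
class PlantModel:
    """A single simulated plant: the seed-potato-rooted organ tree."""

    variety: str
    seed: int | None
    root: OrganNode

    def nodes(self) -> list[OrganNode]:
        return traverse(self, order="preorder")

    def node_count(self) -> int:
        return len(self.nodes())

    def by_class(self, organ_class: str) -> list[OrganNode]:
        return [n for n in self.nodes() if n.organ_class == organ_class]

    def depths_by_class(self, organ_class: str) -> np.ndarray:
        """Trajectory-derived max depths (mm) of every axis of one class."""
        return np.array(
            [axis_depth(n.axis) for n in self.by_class(organ_class)
             if n.axis is not None]
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for n in self.nodes():
            nodes.append({
                "node_id": n.node_id,
                "organ_class": n.organ_class,
                "level": n.level,
                "parent_id": n.parent_id,
                "distance_along_parent": n.distance_along_parent,
                "params": {k: float(v) for k, v in n.params.items()},
                "position": None if n.position is None
                else [float(x) for x in n.position],
                "axis_points": None if n.axis is None
                else np.round(n.axis.points, 6).tolist(),
                "first_child": None if n.first_child is None
                else n.first_child.node_id,
                "next_sibling": None if n.next_sibling is None
                else n.next_sibling.node_id,
            })
        return {"variety": self.variety, "seed": self.seed, "nodes": nodes}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def from_dict(cls, doc: dict) -> "PlantModel":
        by_id: dict[int, OrganNode] = {}
        for nd in doc["nodes"]:
            axis = None
            if nd.get("axis_points") is not None:
                pts = np.asarray(nd["axis_points"], float)
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                axis = RootAxis(
                    points=pts,
                    l_unit=float(seg[0]) if len(seg) else 1.0,
                    theta0_deg=nd["params"].get("axial_angle_deg", 0.0),
                    eta0_deg=nd["params"].get("radial_angle_deg", 0.0),
                    r0=nd["params"].get("initial_radius_mm", 0.0),
                    r_tip=nd["params"].get("tip_radius_mm", 0.0),
                )
            by_id[nd["node_id"]] = OrganNode(
                node_id=nd["node_id"],
                organ_class=nd["organ_class"],
                level=nd["level"],
                params=dict(nd["params"]),
                parent_id=nd.get("parent_id"),
                distance_along_parent=nd.get("distance_along_parent", 0.0),
                axis=axis,
                position=None if nd.get("position") is None
                else np.asarray(nd["position"], float),
            )
        for nd in doc["nodes"]:
            node = by_id[nd["node_id"]]
            if nd.get("first_child") is not None:
                node.first_child = by_id[nd["first_child"]]
            if nd.get("next_sibling") is not None:
                node.next_sibling = by_id[nd["next_sibling"]]
        roots = [n for n in by_id.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValidationError(f"plant document has {len(roots)} roots")
        return cls(variety=doc["variety"], seed=doc.get("seed"),
                   root=roots[0])

    @classmethod
    def load(cls, path: str | Path) -> "PlantModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def traverse(plant: PlantModel, order: str = "preorder") -> list[OrganNode]:
    """Walk the child-sibling links in preorder or level order.

    Raises a structural error if a cycle makes any node reachable twice.
    """
    seen: set[int] = set()

    def _visit(node: OrganNode):
        if id(node) in seen:
            raise ValidationError(
                f"cycle detected at node {node.node_id} during traversal"
            )
        seen.add(id(node))

    if order == "preorder":
        out, stack = [], [plant.root]
        while stack:
            node = stack.pop()
            _visit(node)
            out.append(node)
            stack.extend(reversed(list(node.children())))
        return out
    if order == "levelorder":
        out, frontier = [], [plant.root]
        while frontier:
            nxt = []
            for node in frontier:
                _visit(node)
                out.append(node)
                nxt.extend(node.children())
            frontier = nxt
        return out
    raise ValueError(f"unknown traversal order {order!r}")


def _attach(parent: OrganNode, child: OrganNode) -> None:
    child.parent_id = parent.node_id
    if parent.first_child is None:
        parent.first_child = child
        return
    tail = parent.first_child
    while tail.next_sibling is not None:
        tail = tail.next_sibling
    tail.next_sibling = child


def _sample_root_params(
    db: ParameterDatabase, organ: str, rng: np.random.Generator
) -> dict[str, float]:
    p = {
        name: db.sample(organ, name, rng)
        for name in ("axial_angle_deg", "radial_angle_deg",
                     "initial_radius_mm", "tip_radius_mm", "length_mm",
                     "total_deflection_deg")
    }
    # roots taper: tip radius never exceeds the initial radius
    p["tip_radius_mm"] = min(p["tip_radius_mm"], p["initial_radius_mm"])
    if p["length_mm"] <= 0:
        p["length_mm"] = db.spec(organ, "length_mm").mean() or 1.0
    return p


def build_plant(
    db: ParameterDatabase,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    l_unit: float = 1.0,
) -> PlantModel:
    """Sample one complete plant from a parameter database.

    Organ counts are drawn first, then every organ instance gets its own
    sampled scalar parameters; root and stem axes are generated by the
    growth-unit trajectory model.  Creeping roots and stems attach along the
    vertical underground stem at their sampled rooting distance (clamped to
    the stem height); each creeping stem terminus receives one tuber.  When
    the sampled tuber count is below the stem count the longest stems are
    served first; surplus tubers beyond the stem count are dropped with a
    warning.
    """
    db.validate_complete()
    if rng is None:
        rng = np.random.default_rng(seed)

    ids = iter(range(10 ** 6))

    # seed potato at (0, 0, z0), z positive downward
    seed_params = {
        name: db.sample("seed_potato", name, rng)
        for name in ("length_mm", "width_mm", "height_mm", "burial_depth_mm")
    }
    z0 = seed_params["burial_depth_mm"]
    seed_node = OrganNode(
        node_id=next(ids), organ_class="seed_potato", level=1,
        params=seed_params, position=np.array([0.0, 0.0, z0]),
    )

    stem_params = {
        name: db.sample("underground_stem", name, rng)
        for name in ("bottom_radius_mm", "top_radius_mm", "height_mm")
    }
    stem_params["top_radius_mm"] = min(
        stem_params["top_radius_mm"], stem_params["bottom_radius_mm"]
    )
    h_j = max(stem_params["height_mm"], l_unit)
    stem_params["height_mm"] = h_j
    # the main stem rises vertically from the seed: axial angle 0 == upward
    stem_axis = generate_axis(
        start=(0.0, 0.0, z0), theta0_deg=0.0, eta0_deg=0.0,
        total_length=h_j, l_unit=l_unit,
        r0=stem_params["bottom_radius_mm"],
        r_tip=stem_params["top_radius_mm"],
    )
    stem_node = OrganNode(
        node_id=next(ids), organ_class="underground_stem", level=2,
        params=stem_params, axis=stem_axis,
        position=np.array([0.0, 0.0, z0]),
    )
    _attach(seed_node, stem_node)

    def _grow_root(organ: str, start: np.ndarray, h_g: float) -> OrganNode:
        p = _sample_root_params(db, organ, rng)
        axis = generate_axis(
            start=start,
            theta0_deg=p["axial_angle_deg"],
            eta0_deg=p["radial_angle_deg"],
            total_length=p["length_mm"],
            l_unit=min(l_unit, p["length_mm"]),
            phi_axial_deg=p["total_deflection_deg"],
            r0=p["initial_radius_mm"],
            r_tip=p["tip_radius_mm"],
        )
        return OrganNode(
            node_id=next(ids), organ_class=organ, level=_LEVELS[organ],
            params=p, axis=axis, position=np.asarray(start, float),
            distance_along_parent=h_g,
        )

    # seminal roots spring from the seed potato itself
    n_seminal = db.sample_count("seminal_root", rng)
    for _ in range(n_seminal):
        node = _grow_root("seminal_root", np.array([0.0, 0.0, z0]), 0.0)
        _attach(seed_node, node)

    # creeping roots and stems root along the underground stem
    creeping_stems: list[OrganNode] = []
    for organ in ("creeping_root", "creeping_stem"):
        for _ in range(db.sample_count(organ, rng)):
            h_g = float(np.clip(db.sample(organ, "distance_to_seed_mm", rng),
                                0.0, h_j))
            start = np.array([0.0, 0.0, z0 - h_g])
            node = _grow_root(organ, start, h_g)
            _attach(stem_node, node)
            if organ == "creeping_stem":
                creeping_stems.append(node)

    # one tuber at the terminal node of each served creeping stem
    n_tubers = db.sample_count("tuber", rng)
    if n_tubers > len(creeping_stems):
        warnings.warn(
            f"sampled {n_tubers} tubers but only {len(creeping_stems)} "
            "creeping stems; dropping the surplus",
            stacklevel=2,
        )
        n_tubers = len(creeping_stems)
    by_length = sorted(
        creeping_stems, key=lambda s: s.params["length_mm"], reverse=True
    )
    for stem in by_length[:n_tubers]:
        t_params = {
            name: db.sample("tuber", name, rng)
            for name in ("length_mm", "width_mm", "height_mm")
        }
        tuber = OrganNode(
            node_id=next(ids), organ_class="tuber", level=4,
            params=t_params, position=stem.axis.points[-1].copy(),
        )
        _attach(stem, tuber)

    return PlantModel(variety=db.variety, seed=seed, root=seed_node)
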