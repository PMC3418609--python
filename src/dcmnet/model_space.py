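"""The 7-region network and the 16-model candidate space.

Regions: OP, MT/V5, pSTS, aIPS, IPL, PMv, S/M1.  Baseline coupling is
bidirectional within the execution-related set {S/M1, IPL, PMv, aIPS} and
within the observation-related set {pSTS, IPL, aIPS, MT/V5}, plus a single
driving edge OP->MT/V5 (23 directed edges).  The PMv<->pSTS pair is varied
across models (mutual / PMv->pSTS / pSTS->PMv / absent), crossed with four
direct-input patterns (exec->PMv and hand->pSTS both / PMv only / pSTS only /
neither).  A task input always drives OP.  Both modulatory factors
(Execution, Hand observation) modulate every baseline edge of a model.

Model numbering is row-major over (connection pattern x input pattern) with
model 1 = mutual connection + dual input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "REGIONS",
    "REGION_COORDS_MNI",
    "ModelSpec",
    "ModelSpace",
    "FamilyPartition",
    "base_graph",
    "enumerate_models",
    "partitions",
    "CONNECTION_PATTERNS",
    "INPUT_PATTERNS",
]

REGIONS: tuple[str, ...] = ("OP", "MT/V5", "pSTS", "aIPS", "IPL", "PMv", "S/M1")

#: Group-level ROI peak coordinates (MNI, mm).
REGION_COORDS_MNI: dict[str, tuple[float, float, float]] = {
    "OP": (-22.0, -100.0, 4.0),
    "MT/V5": (-50.0, -72.0, 0.0),
    "pSTS": (-50.0, -64.0, 4.0),
    "aIPS": (-38.0, -42.0, 60.0),
    "IPL": (-56.0, -18.0, 40.0),
    "PMv": (-58.0, 6.0, 28.0),
    "S/M1": (-40.0, -20.0, 58.0),
}

EXEC_CLIQUE = ("S/M1", "IPL", "PMv", "aIPS")
OBS_CLIQUE = ("pSTS", "IPL", "aIPS", "MT/V5")

#: PMv<->pSTS patterns, in model-numbering order.
CONNECTION_PATTERNS: tuple[str, ...] = ("mutual", "pmv_to_psts", "psts_to_pmv", "none")
#: Direct-input patterns, in model-numbering order.
INPUT_PATTERNS: tuple[str, ...] = ("dual", "pmv_only", "psts_only", "none")

_EXTRA_EDGES = {
    "mutual": (("PMv", "pSTS"), ("pSTS", "PMv")),
    "pmv_to_psts": (("PMv", "pSTS"),),
    "psts_to_pmv": (("pSTS", "PMv"),),
    "none": (),
}

_EXTRA_INPUTS = {
    "dual": (("exec", "PMv"), ("hand", "pSTS")),
    "pmv_only": (("exec", "PMv"),),
    "psts_only": (("hand", "pSTS"),),
    "none": (),
}

Edge = tuple[str, str]  # (from, to), directed


def base_graph() -> frozenset[Edge]:
    """The 23 directed baseline edges shared by every model (no PMv-pSTS)."""
    edges: set[Edge] = set()
    for clique in (EXEC_CLIQUE, OBS_CLIQUE):
        for a in clique:
            for b in clique:
                if a != b:
                    edges.add((a, b))
    edges.add(("OP", "MT/V5"))
    return frozenset(edges)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: enabled A edges, B masks per factor, C inputs."""

    model_id: int
    connection_pattern: str
    input_pattern: str
    a_edges: frozenset[Edge]
    b_edges: dict  # factor name -> frozenset[Edge]
    c_inputs: frozenset[tuple[str, str]]  # (input name, target region)

    def __post_init__(self) -> None:
        for factor, mask in self.b_edges.items():
            if not mask <= self.a_edges:
                raise ValueError(f"B mask for {factor} not a subset of A edges")
        if ("task", "OP") not in self.c_inputs:
            raise ValueError("every model must drive OP with the task input")
        for frm, to in self.a_edges:
            if frm == to:
                raise ValueError("self-edges are not allowed in the edge mask")

    @property
    def n_a_edges(self) -> int:
        return len(self.a_edges)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "connection_pattern": self.connection_pattern,
            "input_pattern": self.input_pattern,
            "a_edges": sorted(self.a_edges),
            "b_edges": {k: sorted(v) for k, v in sorted(self.b_edges.items())},
            "c_inputs": sorted(self.c_inputs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            model_id=int(d["model_id"]),
            connection_pattern=d["connection_pattern"],
            input_pattern=d["input_pattern"],
            a_edges=frozenset(tuple(e) for e in d["a_edges"]),
            b_edges={k: frozenset(tuple(e) for e in v) for k, v in d["b_edges"].items()},
            c_inputs=frozenset(tuple(e) for e in d["c_inputs"]),
        )


def _make_model(model_id: int, conn: str, inp: str) -> ModelSpec:
    a = frozenset(base_graph() | set(_EXTRA_EDGES[conn]))
    # both factors modulate the full baseline edge set of the model
    b = {"exec": a, "hand": a}
    c = frozenset({("task", "OP")} | set(_EXTRA_INPUTS[inp]))
    return ModelSpec(
        model_id=model_id,
        connection_pattern=conn,
        input_pattern=inp,
        a_edges=a,
        b_edges=b,
        c_inputs=c,
    )


@dataclass(frozen=True)
class ModelSpace:
    models: tuple[ModelSpec, ...]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, model_id: int) -> ModelSpec:
        """Look up by 1-based model id."""
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    def subset(self, model_ids) -> "ModelSpace":
        return ModelSpace(models=tuple(self[i] for i in model_ids))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([m.to_dict() for m in self.models], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelSpace":
        with open(path) as fh:
            return cls(models=tuple(ModelSpec.from_dict(d) for d in json.load(fh)))


def enumerate_models() -> ModelSpace:
    """All 16 models: (connection pattern) x (input pattern), row-major."""
    models = []
    mid = 1
    for conn in CONNECTION_PATTERNS:
        for inp in INPUT_PATTERNS:
            models.append(_make_model(mid, conn, inp))
            mid += 1
    return ModelSpace(models=tuple(models))


@dataclass(frozen=True)
class FamilyPartition:
    """Assignment of each model id to exactly one named family."""

    name: str
    families: dict  # family name -> tuple of model ids

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for fam, ids in self.families.items():
            if not ids:
                raise ValueError(f"family {fam!r} is empty")
            overlap = seen & set(ids)
            if overlap:
                raise ValueError(f"models {sorted(overlap)} assigned twice")
            seen |= set(ids)

    @property
    def model_ids(self) -> frozenset[int]:
        return frozenset(i for ids in self.families.values() for i in ids)

    def family_of(self, model_id: int) -> str:
        for fam, ids in self.families.items():
            if model_id in ids:
                return fam
        raise KeyError(model_id)

    def restrict(self, model_ids) -> "FamilyPartition":
        """Partition induced on a subset of models (empty families dropped)."""
        keep = set(model_ids)
        fams = {
            fam: tuple(i for i in ids if i in keep)
            for fam, ids in self.families.items()
        }
        fams = {fam: ids for fam, ids in fams.items() if ids}
        return FamilyPartition(name=self.name, families=fams)


def partitions(space: ModelSpace | None = None) -> tuple[FamilyPartition, FamilyPartition]:
    """The two 4-family partitions: by input pattern, by PMv-pSTS pattern."""
    if space is None:
        space = enumerate_models()
    by_input: dict[str, list[int]] = {p: [] for p in INPUT_PATTERNS}
    by_conn: dict[str, list[int]] = {p: [] for p in CONNECTION_PATTERNS}
    for m in space:
        by_input[m.input_pattern].append(m.model_id)
        by_conn[m.connection_pattern].append(m.model_id)
    return (
        FamilyPartition(name="input", families={k: tuple(v) for k, v in by_input.items()}),
        FamilyPartition(name="connection", families={k: tuple(v) for k, v in by_conn.items()}),
    )


def to_dot(model: ModelSpec) -> str:
    """GraphViz dot rendering of one model (documentation aid)."""
    lines = [f'digraph "model_{model.model_id}" {{']
    for r in REGIONS:
        lines.append(f'  "{r}";')
    for frm, to in sorted(model.a_edges):
        lines.append(f'  "{frm}" -> "{to}";')
    for inp, target in sorted(model.c_inputs):
        lines.append(f'  "u_{inp}" [shape=box]; "u_{inp}" -> "{target}" [style=dashed];')
    lines.append("}")
    return "\n".join(lines)
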