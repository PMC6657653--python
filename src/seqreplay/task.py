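"""Task structures: state sets, transition matrices and factor labels.

Two designs are supported.  In both, eight states form two true
("rule-defined") chains of four::

    A -> B -> C -> D        states 0..3  (sequence 1)
    A'-> B'-> C'-> D'       states 4..7  (sequence 2)

The *visual* order is the scrambled presentation stream.  In design
``study1`` the stream preserves every pairwise transition of the true
chains but never chains them beyond length two.  In design ``study2``
the stream shares no directed pairwise transition with the true chains
and alternates between the two sequences within each presentation stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_STATES = 8
CHAIN_LENGTH = 4
STATE_ALIASES = ("A", "B", "C", "D", "A'", "B'", "C'", "D'")

#: Study 1 presentation stages, each a run of four stimuli shown
#: consecutively: [CD, C'D'], [AB, A'B'], [BC, B'C'].
_STUDY1_STAGES = ((2, 3, 6, 7), (0, 1, 4, 5), (1, 2, 5, 6))

_MAX_REJECTION_DRAWS = 100_000


def chain_transition_matrix(chains: list[list[int]], n_states: int) -> np.ndarray:
    """Binary transition matrix with entry (i, j) = 1 iff j follows i."""
    P = np.zeros((n_states, n_states))
    for chain in chains:
        for i, j in zip(chain[:-1], chain[1:]):
            P[i, j] = 1.0
    return P


def edges_of(P: np.ndarray) -> set[tuple[int, int]]:
    """Directed edge set of a binary transition matrix."""
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(P))}


def validate_transition_matrix(P: np.ndarray, *, chain: bool = False) -> None:
    """Raise ``ValueError`` if *P* is not a valid binary transition matrix.

    With ``chain=True`` additionally require row sums <= 1 and zero
    diagonal as demanded for chain structures.
    """
    P = np.asarray(P)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"transition matrix must be square, got {P.shape}")
    if not np.isin(P, (0.0, 1.0)).all():
        raise ValueError("transition matrix must be binary")
    if np.trace(P) != 0:
        raise ValueError("transition matrix must have zero diagonal")
    if chain and (P.sum(axis=1) > 1).any():
        raise ValueError("chain transition matrix must have row sums <= 1")


@dataclass
class FactorMap:
    """Partition of the states by ordinal position and by sequence."""

    position_groups: dict[int, set[int]]
    sequence_groups: dict[int, set[int]]


@dataclass
class StateSpec:
    """State set of one design with its two hypothesis matrices."""

    n_states: int
    labels: tuple[str, ...]
    visual_order: np.ndarray
    rule_order: np.ndarray
    sequence_of: dict[int, int]
    position_of: dict[int, int]
    #: presentation stream as stages (runs of consecutively shown states)
    stages: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        validate_transition_matrix(self.rule_order, chain=True)
        validate_transition_matrix(self.visual_order)

    @property
    def chains(self) -> list[list[int]]:
        """The two rule-defined chains in order, grouped by sequence."""
        out = []
        for seq in sorted(set(self.sequence_of.values())):
            members = [s for s, q in self.sequence_of.items() if q == seq]
            out.append(sorted(members, key=lambda s: self.position_of[s]))
        return out

    def to_json(self) -> str:
        doc = {
            "n_states": self.n_states,
            "labels": list(self.labels),
            "visual_edges": sorted(edges_of(self.visual_order)),
            "rule_edges": sorted(edges_of(self.rule_order)),
            "sequence_of": {str(k): v for k, v in self.sequence_of.items()},
            "position_of": {str(k): v for k, v in self.position_of.items()},
            "stages": [list(s) for s in self.stages],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StateSpec":
        doc = json.loads(text)
        n = doc["n_states"]
        vis = np.zeros((n, n))
        for i, j in doc["visual_edges"]:
            vis[i, j] = 1.0
        rule = np.zeros((n, n))
        for i, j in doc["rule_edges"]:
            rule[i, j] = 1.0
        return cls(
            n_states=n,
            labels=tuple(doc["labels"]),
            visual_order=vis,
            rule_order=rule,
            sequence_of={int(k): v for k, v in doc["sequence_of"].items()},
            position_of={int(k): v for k, v in doc["position_of"].items()},
            stages=tuple(tuple(s) for s in doc["stages"]),
        )


def _stage_edges(stages) -> set[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    for stage in stages:
        out.update(zip(stage[:-1], stage[1:]))
    return out


def _base_maps() -> tuple[dict[int, int], dict[int, int]]:
    sequence_of = {s: 1 if s < CHAIN_LENGTH else 2 for s in range(N_STATES)}
    position_of = {s: s % CHAIN_LENGTH + 1 for s in range(N_STATES)}
    return sequence_of, position_of


def _study2_stages(rng: np.random.Generator) -> tuple[tuple[int, ...], ...]:
    """Draw an admissible study-2 presentation order by rejection sampling.

    A permutation of the 8 states, split into two stages of four, is
    admissible when within each stage consecutive states alternate
    between the two sequences and no within-stage consecutive pair is a
    directed edge of the rule order.
    """
    sequence_of, _ = _base_maps()
    rule_edges = _stage_edges([list(range(4)), list(range(4, 8))])
    for _ in range(_MAX_REJECTION_DRAWS):
        perm = rng.permutation(N_STATES)
        stages = (tuple(int(s) for s in perm[:4]), tuple(int(s) for s in perm[4:]))
        pairs = _stage_edges(stages)
        if pairs & rule_edges:
            continue
        if any(
            sequence_of[a] == sequence_of[b]
            for stage in stages
            for a, b in zip(stage[:-1], stage[1:])
        ):
            continue
        return stages
    raise RuntimeError(
        "rejection sampling failed to find an admissible study-2 order"
    )  # pragma: no cover - cannot occur for 8 states


def make_study_structure(design: str, seed: int = 0) -> StateSpec:
    """Construct the :class:`StateSpec` for ``study1`` or ``study2``.

    ``study1`` uses the fixed stage layout [CD, C'D'], [AB, A'B'],
    [BC, B'C'].  ``study2`` draws a uniformly random admissible
    presentation order (see :func:`_study2_stages`); *seed* controls the
    draw.
    """
    sequence_of, position_of = _base_maps()
    rule = chain_transition_matrix([[0, 1, 2, 3], [4, 5, 6, 7]], N_STATES)
    if design == "study1":
        stages = _STUDY1_STAGES
    elif design == "study2":
        stages = _study2_stages(np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown design {design!r}; expected 'study1' or 'study2'")
    visual = np.zeros((N_STATES, N_STATES))
    for i, j in _stage_edges(stages):
        visual[i, j] = 1.0
    return StateSpec(
        n_states=N_STATES,
        labels=STATE_ALIASES,
        visual_order=visual,
        rule_order=rule,
        sequence_of=sequence_of,
        position_of=position_of,
        stages=tuple(tuple(s) for s in stages),
    )


def position_transition_matrix() -> np.ndarray:
    """Single chain 1 -> 2 -> 3 -> 4 over the four position codes."""
    return chain_transition_matrix([[0, 1, 2, 3]], 4)


def factor_labels(spec: StateSpec) -> FactorMap:
    """Group states by position (4 groups of 2) and sequence (2 groups of 4)."""
    position_groups: dict[int, set[int]] = {}
    sequence_groups: dict[int, set[int]] = {}
    for s in range(spec.n_states):
        position_groups.setdefault(spec.position_of[s], set()).add(s)
        sequence_groups.setdefault(spec.sequence_of[s], set()).add(s)
    return FactorMap(position_groups=position_groups, sequence_groups=sequence_groups)
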