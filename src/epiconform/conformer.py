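"""Map cross-linked pairs onto candidate conformational states.

A lysine pair can only be cross-linked by DSS when its Calpha-Calpha
distance fits within the reagent's maximal span (30 A); distances far
below the optimum are also unfavourable because the short gap
constrains where the two side chains can meet.  Those two facts are
formalized as a trapezoidal cross-linking propensity kernel over
distance d:

    f(d) = 0                            d <= d_low_floor or d >= max_span
           rises linearly 0 -> 1       d_low_floor .. d_low_opt
           1                            d_low_opt .. d_high_opt
           falls linearly 1 -> 0        d_high_opt .. max_span

With defaults d_low_floor = 5 A, d_low_opt = 12 A, d_high_opt = 25 A,
max_span = 30 A: the state preferred by the condition with the higher
%XL is the compatible (within-span) state of highest propensity.  Ties
within ``tie_epsilon`` are reported as "indeterminate"; the kernel is a
package construct whose defaults reproduce the published qualitative
calls, and every input is echoed in the call's rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epiconform.crosslink import PairKey
from epiconform.io import Trajectory


@dataclass
class StateDistanceTable:
    """Calpha-Calpha distances of cross-linked pairs in one candidate state."""

    state_label: str
    distances: dict[PairKey, float]

    def __post_init__(self) -> None:
        for pair, d in self.distances.items():
            if not np.isfinite(d) or d < 0:
                raise ValueError(f"invalid distance {d} for {pair}")

    @classmethod
    def from_structure(cls, state_label: str, traj: Trajectory,
                       pairs: list[PairKey], frame: int = 0,
                       chain: str | None = None) -> "StateDistanceTable":
        return cls(state_label, {
            p: ca_distance(traj, p.residue_i, p.residue_j,
                           frame=frame, chain=chain)
            for p in pairs
        })


@dataclass(frozen=True)
class PropensityKernel:
    """Trapezoidal cross-linking propensity over Calpha distance (see
    module docstring); bounded in [0, 1], continuous, 0 beyond max_span."""

    d_low_floor: float = 5.0
    d_low_opt: float = 12.0
    d_high_opt: float = 25.0
    max_span: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.d_low_floor < self.d_low_opt
                <= self.d_high_opt < self.max_span):
            raise ValueError(
                "kernel requires 0 <= d_low_floor < d_low_opt <= "
                "d_high_opt < max_span"
            )

    def __call__(self, d: float) -> float:
        return float(np.interp(
            d,
            [self.d_low_floor, self.d_low_opt, self.d_high_opt, self.max_span],
            [0.0, 1.0, 1.0, 0.0],
            left=0.0, right=0.0,
        ))


@dataclass
class ConformerCall:
    """Preferred conformational state for the condition with higher %XL."""

    pair: PairKey
    condition_with_higher_xl: str
    compatible_states: list[str]
    preferred_state: str  # a state label or "indeterminate"
    rationale: dict


def ca_distance(traj: Trajectory, residue_i: int, residue_j: int,
                frame: int = 0, chain: str | None = None) -> float:
    """Euclidean Calpha-Calpha distance (A) between two residues in one frame."""
    pi = traj.residue_index(residue_i, chain)
    pj = traj.residue_index(residue_j, chain)
    return float(np.linalg.norm(traj.frames[frame, pi] - traj.frames[frame, pj]))


def validate_spans(table: StateDistanceTable,
                   max_span: float = 30.0) -> pd.DataFrame:
    """Check every pair's distance against the cross-linker's maximal span.

    Returns a DataFrame (pair coordinates, distance, ``within_span``);
    ``df.attrs["n_violations"]`` carries the summary count.  An empty
    table yields an empty report.
    """
    if max_span < 0:
        raise ValueError("max_span must be non-negative")
    rows = [
        {
            "state": table.state_label,
            "protein_id": p.protein_id,
            "residue_i": p.residue_i,
            "residue_j": p.residue_j,
            "distance": d,
            "within_span": d <= max_span,
        }
        for p, d in sorted(table.distances.items())
    ]
    df = pd.DataFrame(rows, columns=["state", "protein_id", "residue_i",
                                     "residue_j", "distance", "within_span"])
    df.attrs["n_violations"] = int((~df["within_span"]).sum()) if len(df) else 0
    return df


def classify_pair_preference(pair: PairKey,
                             xl_by_condition: dict[str, float],
                             state_tables: list[StateDistanceTable],
                             kernel: PropensityKernel = PropensityKernel(),
                             tie_epsilon: float = 0.05) -> ConformerCall:
    """Call the conformational state preferred by the higher-%XL condition.

    For the condition whose mean %XL is highest, each candidate state is
    scored with the propensity kernel at the pair's distance in that
    state; states beyond the cross-linker's span are incompatible.  The
    compatible state with the highest propensity wins; a propensity gap
    below ``tie_epsilon`` (or no compatible state) is "indeterminate".
    """
    if len(state_tables) < 2:
        raise ValueError("need at least two candidate states")
    if len(xl_by_condition) < 2:
        raise ValueError("need at least two conditions")
    higher = max(xl_by_condition, key=lambda c: xl_by_condition[c])
    distances = {}
    propensities = {}
    compatible = []
    for table in state_tables:
        if pair not in table.distances:
            raise KeyError(f"{pair} missing from state {table.state_label!r}")
        d = table.distances[pair]
        distances[table.state_label] = d
        propensities[table.state_label] = kernel(d)
        if d <= kernel.max_span:
            compatible.append(table.state_label)
    rationale = {
        "xl_by_condition": dict(xl_by_condition),
        "distances": distances,
        "propensities": propensities,
        "kernel": {
            "d_low_floor": kernel.d_low_floor, "d_low_opt": kernel.d_low_opt,
            "d_high_opt": kernel.d_high_opt, "max_span": kernel.max_span,
        },
        "tie_epsilon": tie_epsilon,
    }
    if not compatible:
        preferred = "indeterminate"
    else:
        ranked = sorted(compatible, key=lambda s: propensities[s], reverse=True)
        if len(ranked) > 1 and (propensities[ranked[0]]
                                - propensities[ranked[1]]) < tie_epsilon:
            preferred = "indeterminate"
        else:
            preferred = ranked[0]
    return ConformerCall(pair=pair, condition_with_higher_xl=higher,
                         compatible_states=compatible,
                         preferred_state=preferred, rationale=rationale)
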