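"""Range state space: subsets of areas up to a maximum range size plus the
null range. State ordering is fixed (size, then lexicographic by area index)
so serialized results are stable across runs."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .areas import AreaScheme

__all__ = ["RangeStateSpace", "build_state_space"]

_MAX_AREAS = 12


@dataclass(frozen=True)
class RangeStateSpace:
    scheme: AreaScheme
    max_range_size: int
    states: tuple[frozenset, ...]   # states[0] == frozenset() (the null range)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def k(self) -> int:
        return self.scheme.k

    def index(self, areas) -> int:
        """State index for an iterable of area labels (or a single label)."""
        if isinstance(areas, str):
            areas = [areas]
        s = frozenset(self.scheme.index(a) for a in areas)
        try:
            return self.states.index(s)
        except ValueError:
            raise KeyError(f"range {sorted(areas)} not in state space") from None

    def labels(self, state_idx: int) -> tuple[str, ...]:
        return tuple(self.scheme.labels[i] for i in sorted(self.states[state_idx]))

    def label_string(self, state_idx: int) -> str:
        labs = self.labels(state_idx)
        return "+".join(labs) if labs else "(null)"


def build_state_space(
    scheme: AreaScheme, max_range_size: int | None = None, force: bool = False
) -> RangeStateSpace:
    """All non-empty subsets of areas up to ``max_range_size``, plus the
    null range at index 0.

    With K areas and no cap there are 2**K states. K > 12 is refused unless
    ``force`` is given (state explosion).
    """
    k = scheme.k
    if max_range_size is None:
        max_range_size = k
    if not 1 <= max_range_size <= k:
        raise ValueError(f"max_range_size must be in [1, {k}], got {max_range_size}")
    if k > _MAX_AREAS and not force:
        raise ValueError(f"{k} areas would give 2^{k} states; pass force=True to allow")
    states = [frozenset()]
    for size in range(1, max_range_size + 1):
        for combo in combinations(range(k), size):
            states.append(frozenset(combo))
    return RangeStateSpace(scheme, max_range_size, tuple(states))
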