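"""Three-band-probe chromosome fold configurations.

Three sub-arm probes (centromere-proximal, middle, telomere-proximal) tiled
along one chromosome arm define a 3-bit contact state: cen–mid, mid–tel and
cen–tel touching.  A configuration is *closed* when the centromere- and
telomere-proximal probes touch (long-range arm folding), *open* otherwise —
regardless of the other two contacts.  Eight states exist, four open and four
closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Iterable

import numpy as np

from .metrics import in_contact

__all__ = [
    "ConfigurationState",
    "ConfigurationFrequencies",
    "classify_configuration",
    "configuration_frequencies",
    "ALL_STATES",
    "CLOSED_STATE_IDS",
    "OPEN_STATE_IDS",
]


@dataclass(frozen=True)
class ConfigurationState:
    """Contact state of the cen/mid/tel band probes of one chromosome arm."""

    cen_mid: bool
    mid_tel: bool
    cen_tel: bool

    @property
    def contacts(self) -> tuple[bool, bool, bool]:
        return (self.cen_mid, self.mid_tel, self.cen_tel)

    @property
    def state_id(self) -> int:
        """Binary encoding 0–7 with the cen–tel contact as the high bit."""
        return 4 * int(self.cen_tel) + 2 * int(self.mid_tel) + int(self.cen_mid)

    @property
    def closed(self) -> bool:
        """Closed ⇔ the cen and tel probes touch."""
        return self.cen_tel

    @classmethod
    def from_state_id(cls, state_id: int) -> "ConfigurationState":
        if not 0 <= state_id <= 7:
            raise ValueError(f"state_id must be 0–7, got {state_id}")
        return cls(cen_mid=bool(state_id & 1), mid_tel=bool(state_id & 2), cen_tel=bool(state_id & 4))


ALL_STATES = tuple(ConfigurationState.from_state_id(i) for i in range(8))
CLOSED_STATE_IDS = frozenset(s.state_id for s in ALL_STATES if s.closed)
OPEN_STATE_IDS = frozenset(s.state_id for s in ALL_STATES if not s.closed)


def classify_configuration(cen_mask, mid_mask, tel_mask, *, adjacency: bool = True) -> ConfigurationState:
    """Classify the fold configuration of one cell's three band probes.

    "Touching" reuses the territory contact rule (overlap or 26-adjacency by
    default) for internal consistency.  If a probe segments into multiple
    components the caller passes their union.  Any empty probe mask makes the
    cell unclassifiable (raises), never silently open.
    """
    masks = {"cen": cen_mask, "mid": mid_mask, "tel": tel_mask}
    for name, m in masks.items():
        if m is None:
            raise ValueError(f"missing {name} probe mask: configuration unclassifiable")
        if not np.any(np.asarray(getattr(m, "voxels", m), dtype=bool)):
            raise ValueError(f"empty {name} probe mask: configuration unclassifiable")
    return ConfigurationState(
        cen_mid=in_contact(masks["cen"], masks["mid"], adjacency=adjacency),
        mid_tel=in_contact(masks["mid"], masks["tel"], adjacency=adjacency),
        cen_tel=in_contact(masks["cen"], masks["tel"], adjacency=adjacency),
    )


@dataclass
class ConfigurationFrequencies:
    """Population frequencies of the eight fold states."""

    counts: np.ndarray  # length 8, by state_id
    n: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def closed_fraction(self) -> float:
        return float(sum(self.counts[i] for i in CLOSED_STATE_IDS)) / self.n

    @property
    def open_fraction(self) -> float:
        return float(sum(self.counts[i] for i in OPEN_STATE_IDS)) / self.n


def configuration_frequencies(states: Iterable[ConfigurationState | int]) -> ConfigurationFrequencies:
    """Tally per-state fractions (sum to 1) and the open/closed split.

    Accepts :class:`ConfigurationState` objects or raw state ids; raw counts
    are retained for downstream exact tests.
    """
    ids = [s if isinstance(s, (int, np.integer)) else s.state_id for s in states]
    if not ids:
        raise ValueError("configuration_frequencies needs at least one classified cell")
    counter = Counter(int(i) for i in ids)
    if any(not 0 <= i <= 7 for i in counter):
        raise ValueError("state ids must be 0–7")
    counts = np.array([counter.get(i, 0) for i in range(8)], dtype=int)
    return ConfigurationFrequencies(counts=counts, n=len(ids))
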