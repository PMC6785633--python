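"""The circadian sampling grid.

The default design matches a feeding-entrainment time course: samples every
6 h from CT0 to CT30 (6 time points spanning 30 h), with biological
replicates at each circadian time (CT). A non-synchronized (NS) sample, when
present, sits outside the grid and is excluded from rhythm fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

NS_LABEL = "NS"


@dataclass(frozen=True)
class TimeGrid:
    """Ordered circadian time points with replicate labels."""

    ct_labels: tuple[str, ...]
    times_h: tuple[float, ...]
    replicates: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ct_labels) != len(self.times_h):
            raise ValueError("ct_labels and times_h must have the same length")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("times must be strictly increasing")
        if NS_LABEL in self.ct_labels:
            raise ValueError("the NS sample is outside the grid")

    @classmethod
    def default(cls, n_replicates: int = 2) -> "TimeGrid":
        times = tuple(float(t) for t in range(0, 31, 6))
        labels = tuple(f"CT{int(t)}" for t in times)
        reps = tuple(f"r{i + 1}" for i in range(n_replicates))
        return cls(labels, times, reps)

    @property
    def n_ct(self) -> int:
        return len(self.ct_labels)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def dt(self) -> float:
        """Grid spacing in hours; requires an even grid."""
        diffs = {round(b - a, 9) for a, b in zip(self.times_h, self.times_h[1:])}
        if len(diffs) != 1:
            raise ValueError("grid is not evenly spaced")
        return diffs.pop()

    def samples(self) -> Iterator[tuple[str, str]]:
        for ct in self.ct_labels:
            for rep in self.replicates:
                yield ct, rep

    def sample_name(self, ct: str, rep: str) -> str:
        return f"{ct}_{rep}"
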