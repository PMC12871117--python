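"""Home-cage topology: connected cages with paired RFID antennas on tubes.

Four functionally distinct cages (nest with shelters, food/water cage,
enrichment cage, and the empty cage giving access to the operant box) are
joined by transparent tubes.  Each tube carries two circular antennas, one
near each end; a subject traversing a tube fires the pair in order, and the
second detection of a consistent pair places the subject in the destination
cage.  The default layout is a linear chain with three tubes and six
antennas.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ConfigError

CAGES = ("nest", "food", "enrichment", "task_access")


@dataclass(frozen=True)
class Tube:
    tube_id: int
    cage_a: str
    cage_b: str
    antenna_a: int  # near cage_a
    antenna_b: int  # near cage_b


@dataclass(frozen=True)
class HomeCageTopology:
    tubes: tuple[Tube, ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for tube in self.tubes:
            for ant in (tube.antenna_a, tube.antenna_b):
                if ant in seen:
                    raise ConfigError(f"antenna {ant} appears on two tubes")
                seen.add(ant)

    @property
    def antenna_ids(self) -> frozenset[int]:
        return frozenset(
            a for t in self.tubes for a in (t.antenna_a, t.antenna_b)
        )

    @property
    def cages(self) -> tuple[str, ...]:
        names: list[str] = []
        for t in self.tubes:
            for c in (t.cage_a, t.cage_b):
                if c not in names:
                    names.append(c)
        return tuple(names)

    def neighbors(self, cage: str) -> list[str]:
        out = []
        for t in self.tubes:
            if t.cage_a == cage:
                out.append(t.cage_b)
            elif t.cage_b == cage:
                out.append(t.cage_a)
        return out

    def antenna_pair(self, src: str, dst: str) -> tuple[int, int]:
        """Ordered (near-src, near-dst) antenna pair for the tube src -> dst."""
        for t in self.tubes:
            if (t.cage_a, t.cage_b) == (src, dst):
                return t.antenna_a, t.antenna_b
            if (t.cage_b, t.cage_a) == (src, dst):
                return t.antenna_b, t.antenna_a
        raise ConfigError(f"no tube between {src!r} and {dst!r}")

    def destination_of(self, first_antenna: int, second_antenna: int) -> str | None:
        """Cage entered when the two antennas of one tube fire in this order,
        or ``None`` if the pair is not a consistent traversal."""
        for t in self.tubes:
            if (first_antenna, second_antenna) == (t.antenna_a, t.antenna_b):
                return t.cage_b
            if (first_antenna, second_antenna) == (t.antenna_b, t.antenna_a):
                return t.cage_a
        return None

    def same_tube(self, a: int, b: int) -> bool:
        return any(
            {a, b} == {t.antenna_a, t.antenna_b} and a != b for t in self.tubes
        )

    def path(self, src: str, dst: str) -> list[str]:
        """Shortest cage sequence from src to dst (BFS; small graphs)."""
        if src == dst:
            return [src]
        frontier = [[src]]
        seen = {src}
        while frontier:
            nxt = []
            for p in frontier:
                for nb in self.neighbors(p[-1]):
                    if nb in seen:
                        continue
                    if nb == dst:
                        return p + [nb]
                    seen.add(nb)
                    nxt.append(p + [nb])
            frontier = nxt
        raise ConfigError(f"no path between {src!r} and {dst!r}")


def default_topology() -> HomeCageTopology:
    """Linear chain nest - food - enrichment - task_access (3 tubes, 6 antennas)."""
    return HomeCageTopology(
        tubes=(
            Tube(0, "nest", "food", 1, 2),
            Tube(1, "food", "enrichment", 3, 4),
            Tube(2, "enrichment", "task_access", 5, 6),
        )
    )
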