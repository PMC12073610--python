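"""Rectangle primitive shared by ROIs, white-standard patches and scene layout.

Convention everywhere in the package: row-major, 0-based, half-open
rectangles ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Rect:
    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self) -> None:
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError(f"empty or inverted rectangle: {self}")
        if self.r0 < 0 or self.c0 < 0:
            raise ValueError(f"negative rectangle origin: {self}")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    def within(self, shape: tuple[int, ...]) -> bool:
        """True if the rectangle fits inside a raster of the given shape."""
        return self.r1 <= shape[0] and self.c1 <= shape[1]

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.r0 < other.r1
            and other.r0 < self.r1
            and self.c0 < other.c1
            and other.c0 < self.c1
        )
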