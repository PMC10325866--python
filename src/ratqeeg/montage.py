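"""Cortical screw-electrode montage of the 12-channel rat recording setup.

Coordinates are skull-surface positions in millimetres relative to bregma:
``anterior`` (positive = rostral) and ``lateral`` (positive = right).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ElectrodeLayout:
    """A named set of scalp channels with flattened skull coordinates.

    Parameters
    ----------
    labels : list of str
        Channel names in canonical order.
    coords : dict
        Mapping label -> (anterior_mm, lateral_mm).
    reference_label, ground_label : str
        Names of the reference and ground electrodes (not part of ``labels``).
    """

    labels: tuple[str, ...]
    coords: dict[str, tuple[float, float]] = field(compare=False)
    reference_label: str = "REF"
    ground_label: str = "GND"

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate channel labels")
        missing = [l for l in self.labels if l not in self.coords]
        if missing:
            raise ValueError(f"coordinates missing for channels: {missing}")
        pts = [self.coords[l] for l in self.labels]
        if len(set(pts)) != len(pts):
            raise ValueError("electrode coordinates must be distinct")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def positions(self) -> "list[tuple[float, float]]":
        """(anterior, lateral) pairs in label order."""
        return [self.coords[l] for l in self.labels]

    def homologous_pairs(self) -> "list[tuple[str, str]]":
        """Left/right electrode pairs (same anterior, mirrored lateral)."""
        pairs = []
        for a in self.labels:
            for b in self.labels:
                if a >= b:
                    continue
                ca, cb = self.coords[a], self.coords[b]
                if ca[0] == cb[0] and ca[1] == -cb[1] and ca[1] != 0:
                    pairs.append((a, b) if ca[1] < 0 else (b, a))
        return pairs

    def mirrored(self) -> "ElectrodeLayout":
        """Layout with the lateral axis flipped (left/right exchanged)."""
        return ElectrodeLayout(
            labels=self.labels,
            coords={l: (a, -s) for l, (a, s) in self.coords.items()},
            reference_label=self.reference_label,
            ground_label=self.ground_label,
        )


#: Skull coordinates of the 12 recording sites (mm from bregma).
#: Odd indices are left hemisphere (negative lateral), even are right.
_SITES = {
    "F3": (5.0, -2.0),   # frontal association cortex
    "F4": (5.0, 2.0),
    "C3": (2.2, -3.2),   # primary motor cortex
    "C4": (2.2, 3.2),
    "P3": (-3.8, -2.5),  # medial parietal association cortex
    "P4": (-3.8, 2.5),
    "P5": (-4.5, -4.5),  # lateral parietal association cortex
    "P6": (-4.5, 4.5),
    "T3": (-3.6, -7.2),  # secondary auditory cortex
    "T4": (-3.6, 7.2),
    "T5": (-8.3, -5.8),  # temporal association cortex
    "T6": (-8.3, 5.8),
}


def default_layout() -> ElectrodeLayout:
    """The standard 12-site rat skull montage used throughout the pipeline."""
    return ElectrodeLayout(labels=tuple(_SITES), coords=dict(_SITES))


def electrode_pairs(layout: ElectrodeLayout) -> "list[tuple[str, str]]":
    """All unordered channel pairs in canonical (label-order) enumeration."""
    labs = layout.labels
    return [(labs[i], labs[j]) for i in range(len(labs)) for j in range(i + 1, len(labs))]
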