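"""Construct labels and the experimental study designs.

Tissue constructs are stacks of eight 200 µm sections (1.6 mm total) encoded
as 8-character binary strings read top-down: "0" is myocardium, "1" is aortic
tissue standing in for fibrosis. Four study designs are used:

* ``binary``   — pure myocardium vs. pure aorta (2 classes).
* ``depth``    — a 400 µm (two-section) fibrotic inset at successively deeper
  positions, plus the two pure constructs (6 classes).
* ``volume``   — fibrotic volume fraction rising in 12.5% steps (9 classes).
* ``permuted`` — heterogeneous 50/50 arrangements (6 classes).

Each design carries a proximal-credit threshold: a misprediction whose
layer-difference (Hamming) distance from the truth equals the design's
minimal inter-class difference is credited as half correct by the accuracy
statistic in :mod:`fibrospec.evaluation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Tuple

N_LAYERS = 8
LAYER_THICKNESS_UM = 200.0

_DEPTH_CLASSES = (
    "11000000",
    "00110000",
    "00001100",
    "00000011",
    "00000000",
    "11111111",
)
_VOLUME_CLASSES = (
    "00000000",
    "01000000",
    "11000000",
    "11100000",
    "11110000",
    "11111000",
    "11111100",
    "11111110",
    "11111111",
)
_PERMUTED_CLASSES = (
    "11110000",
    "00001111",
    "11001100",
    "00110011",
    "10101010",
    "01010101",
)

STUDY_NAMES = ("binary", "depth", "volume", "permuted")


def validate_label(label: str) -> str:
    """Return ``label`` if it is a valid 8-character binary construct label."""
    if not isinstance(label, str) or len(label) != N_LAYERS:
        raise ValueError(f"construct label must be an {N_LAYERS}-character string: {label!r}")
    if any(c not in "01" for c in label):
        raise ValueError(f"construct label must contain only '0'/'1': {label!r}")
    return label


def hamming_distance(a: str, b: str) -> int:
    """Number of layers at which two construct labels differ (0..8)."""
    validate_label(a)
    validate_label(b)
    return sum(ca != cb for ca, cb in zip(a, b))


def volume_fraction(label: str) -> float:
    """Fraction of fibrotic ("1") layers in a construct, a multiple of 0.125."""
    validate_label(label)
    return label.count("1") / N_LAYERS


@dataclass(frozen=True)
class StudyDesign:
    """A named class set with its proximal threshold and sampling protocol."""

    name: str
    classes: Tuple[str, ...]
    proximal_threshold: int
    n_rebuilds: int = 3
    spectra_per_fiber_per_rebuild: int = 10
    fibers: Tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")

    def __post_init__(self) -> None:
        classes = tuple(validate_label(c) for c in self.classes)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "fibers", tuple(self.fibers))
        if len(set(classes)) != len(classes):
            raise ValueError("study classes must be distinct")
        if not 0 <= self.proximal_threshold <= N_LAYERS:
            raise ValueError("proximal_threshold must be in [0, 8]")
        if self.n_rebuilds < 2:
            raise ValueError("subject-wise hold-out requires n_rebuilds >= 2")
        if self.spectra_per_fiber_per_rebuild < 1:
            raise ValueError("spectra_per_fiber_per_rebuild must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def chance_accuracy(self) -> float:
        return 1.0 / self.n_classes


def min_pairwise_hamming(labels: Sequence[str]) -> int:
    return min(hamming_distance(a, b) for a, b in combinations(labels, 2))


def enumerate_study_classes(
    name: str,
    permuted_classes: Optional[Sequence[str]] = None,
    **protocol,
) -> StudyDesign:
    """Build the :class:`StudyDesign` for one of the four named studies.

    The depth design uses a proximal threshold of 4 layers: the minimal
    difference between two inset positions (a two-section inset moved to an
    adjacent non-overlapping slot changes 4 layers). The volume design uses 1
    (adjacent volume fractions differ by one section). The permuted design
    uses the minimal pairwise distance of its (configurable) class set.

    Parameters
    ----------
    name
        One of ``binary``, ``depth``, ``volume``, ``permuted``.
    permuted_classes
        Optional replacement class set for the permuted study; every member
        must be a 50/50 arrangement.
    protocol
        Overrides for ``n_rebuilds``, ``spectra_per_fiber_per_rebuild``,
        ``fibers``.
    """
    if name == "binary":
        return StudyDesign(name, ("00000000", "11111111"), proximal_threshold=0, **protocol)
    if name == "depth":
        return StudyDesign(name, _DEPTH_CLASSES, proximal_threshold=4, **protocol)
    if name == "volume":
        return StudyDesign(name, _VOLUME_CLASSES, proximal_threshold=1, **protocol)
    if name == "permuted":
        classes = tuple(permuted_classes) if permuted_classes is not None else _PERMUTED_CLASSES
        for c in classes:
            if volume_fraction(c) != 0.5:
                raise ValueError(f"permuted classes must be 50/50 arrangements: {c!r}")
        return StudyDesign(
            name, classes, proximal_threshold=min_pairwise_hamming(classes), **protocol
        )
    raise ValueError(f"unknown study name {name!r}; expected one of {STUDY_NAMES}")


def is_proximal(pred: str, truth: str, design: StudyDesign) -> bool:
    """Whether a misprediction earns proximal (half) credit under a design.

    True iff ``pred != truth`` and their layer difference equals the design's
    proximal threshold (the minimal inter-class difference of the study).
    """
    for lab in (pred, truth):
        if lab not in design.classes:
            raise ValueError(f"label {lab!r} is not a class of study {design.name!r}")
    if pred == truth:
        return False
    return hamming_distance(pred, truth) == design.proximal_threshold
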