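"""The seven-class labelling scheme used throughout the pipeline.

Classes are indexed 0..6 in a fixed order. Each class belongs to one of
three clinical groups used by the per-image evaluation protocol:
``malignant`` (bladder cancer), ``benign`` (post-treatment findings that
are monitored but not resected) and ``healthy`` (normal anatomy and
non-tissue content). Each class also carries an RGB overlay colour;
bladder cancer is cyan and image artifacts are green, the rest of the
palette is a package choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NORMAL = 0
CANCER = 1
BCG_CYSTITIS = 2
TURBT_SCAR = 3
URETERIC_ORIFICE = 4
AIR_BUBBLE = 5
ARTIFACT = 6

_DEFAULT_NAMES = (
    "normal tissue",
    "bladder cancer",
    "BCG cystitis",
    "TURBT scar",
    "ureteric orifice",
    "air bubble",
    "image artifact",
)

_DEFAULT_GROUPS = (
    "healthy",   # normal tissue
    "malignant", # bladder cancer
    "benign",    # BCG cystitis
    "benign",    # TURBT scar
    "healthy",   # ureteric orifice
    "healthy",   # air bubble
    "healthy",   # image artifact
)

# Overlay palette, RGB in [0, 1]. Cancer cyan and artifact green are the
# clinically mandated colours; the others are fixed so overlays are
# reproducible.
_DEFAULT_COLORS = (
    (1.0, 1.0, 1.0),  # normal tissue (never outlined)
    (0.0, 1.0, 1.0),  # bladder cancer: cyan
    (1.0, 0.6, 0.0),  # BCG cystitis: orange
    (1.0, 1.0, 0.0),  # TURBT scar: yellow
    (1.0, 0.0, 1.0),  # ureteric orifice: magenta
    (0.2, 0.4, 1.0),  # air bubble: blue
    (0.0, 1.0, 0.0),  # image artifact: green
)

N_CLASSES = 7
GROUP_NAMES = ("malignant", "benign", "healthy")


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class names with clinical grouping and overlay colours."""

    class_names: tuple[str, ...] = _DEFAULT_NAMES
    group_of: tuple[str, ...] = _DEFAULT_GROUPS
    color_of: tuple[tuple[float, float, float], ...] = _DEFAULT_COLORS

    def __post_init__(self) -> None:
        if not (len(self.class_names) == len(self.group_of) == len(self.color_of) == N_CLASSES):
            raise ValueError(f"scheme must define exactly {N_CLASSES} classes")
        for g in self.group_of:
            if g not in GROUP_NAMES:
                raise ValueError(f"unknown group {g!r}")

    @property
    def n_classes(self) -> int:
        return N_CLASSES

    def classes_in_group(self, group: str) -> tuple[int, ...]:
        return tuple(i for i, g in enumerate(self.group_of) if g == group)

    @property
    def malignant_classes(self) -> tuple[int, ...]:
        return self.classes_in_group("malignant")

    @property
    def benign_classes(self) -> tuple[int, ...]:
        return self.classes_in_group("benign")

    @property
    def healthy_classes(self) -> tuple[int, ...]:
        return self.classes_in_group("healthy")


DEFAULT_SCHEME = ClassScheme()
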