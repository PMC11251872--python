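"""Region-of-interest metadata shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 10 subcortical + 10 cortical regions, in canonical order.
SUBCORTICAL = (
    "Thal-HO",
    "Thal-EPI",
    "Thal-NS",
    "Hippo",
    "Stria",
    "Hypo",
    "Pal",
    "BF",
    "TRN",
    "VTA",
)
CORTICAL = (
    "Ccx",
    "RSP",
    "PPC",
    "TC",
    "OC",
    "SS",
    "VC",
    "MC",
    "Insular",
    "PrL",
)


@dataclass(frozen=True)
class RoiSet:
    """An ordered set of named regions with a cortical/subcortical class.

    Parameters
    ----------
    names
        Ordered region labels; must be unique.
    class_of
        Map ``region -> "cortical" | "subcortical"``, balanced 50/50.
    hemisphere_layout
        Optional map ``region -> tuple of lattice coordinates`` used in voxel
        mode; every labeled voxel must belong to exactly one region.
    """

    names: tuple[str, ...]
    class_of: dict[str, str] = field(repr=False)
    hemisphere_layout: dict[str, tuple[tuple[int, int, int], ...]] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("ROI labels must be unique")
        classes = [self.class_of[n] for n in self.names]
        bad = {c for c in classes if c not in ("cortical", "subcortical")}
        if bad:
            raise ValueError(f"unknown ROI classes: {sorted(bad)}")
        n_c = classes.count("cortical")
        n_s = classes.count("subcortical")
        if n_c != n_s:
            raise ValueError(
                f"expected equal cortical/subcortical counts, got {n_c}/{n_s}"
            )
        if self.hemisphere_layout is not None:
            seen: dict[tuple[int, int, int], str] = {}
            for region, coords in self.hemisphere_layout.items():
                for c in coords:
                    if c in seen:
                        raise ValueError(
                            f"voxel {c} assigned to both {seen[c]} and {region}"
                        )
                    seen[c] = region

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def cortical_idx(self) -> np.ndarray:
        """Indices of cortical regions in canonical order."""
        return np.array(
            [i for i, n in enumerate(self.names) if self.class_of[n] == "cortical"]
        )

    @property
    def subcortical_idx(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.names) if self.class_of[n] == "subcortical"]
        )

    @property
    def is_cortical(self) -> np.ndarray:
        """Boolean mask over the canonical ordering."""
        return np.array([self.class_of[n] == "cortical" for n in self.names])


def default_roi_set() -> RoiSet:
    """The 20-region rat set (10 subcortical then 10 cortical)."""
    names = SUBCORTICAL + CORTICAL
    class_of = {n: "subcortical" for n in SUBCORTICAL}
    class_of.update({n: "cortical" for n in CORTICAL})
    return RoiSet(names=names, class_of=class_of)
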