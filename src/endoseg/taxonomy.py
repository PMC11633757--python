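"""Tissue-class hierarchy and the two regroupings used for training/evaluation.

Pathologists annotate head-and-neck sections with a fine-grained inventory
of histologies.  For modelling, these are merged into six meta classes
(healthy epithelium, tumor stroma, other tissue, necrosis, tumor,
background) and further into the three clinically motivated classes
(background, tissue to resect = tumor + necrosis + tumor stroma, tissue to
preserve = everything benign).  Dysplasia counts as tumor; "other tissue"
absorbs blood vessels, adipose, inflamed stroma, glandular, connective,
muscle and cartilage tissue.

The codebook (label name <-> integer code) ships as a versioned YAML file
in :mod:`endoseg.data`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .images import AnnotationMask

__all__ = [
    "ClassTaxonomy",
    "get_taxonomy",
    "regroup",
    "class_proportions",
    "SIX_CLASS_PRIORS",
]

#: pixel prior of each of the six meta classes in the study cohort.
#: The reported rounded percentages (56/18/10/7/7/1) sum to 99%; they are
#: renormalized proportionally so the priors sum to exactly 1.
_RAW_PRIORS = {
    "background": 0.56,
    "tumor": 0.18,
    "other tissue": 0.10,
    "necrosis": 0.07,
    "tumor stroma": 0.07,
    "healthy epithelium": 0.01,
}
SIX_CLASS_PRIORS: dict[str, float] = {
    k: v / sum(_RAW_PRIORS.values()) for k, v in _RAW_PRIORS.items()
}


@lru_cache(maxsize=1)
def _codebook() -> dict:
    with resources.files("endoseg.data").joinpath("taxonomy.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ClassTaxonomy:
    """One taxonomy level: ordered label names and the map to the next level.

    ``regroup_map`` maps each integer code at this level to the integer code
    of its parent at the next coarser level (``None`` at the coarsest level).
    """

    level: int
    names: tuple[str, ...]
    regroup_map: dict[int, int] | None

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def code(self, name: str) -> int:
        return self.names.index(name)


@lru_cache(maxsize=None)
def get_taxonomy(level: int) -> ClassTaxonomy:
    """Return the taxonomy at a given level (15, 6 or 3)."""
    book = _codebook()
    if level not in book["levels"]:
        raise ValueError(f"unknown taxonomy level {level}; expected 15, 6 or 3")
    names_by_code = book["levels"][level]["names"]
    names = tuple(names_by_code[c] for c in sorted(names_by_code))
    key = {15: "15to6", 6: "6to3", 3: None}[level]
    if key is None:
        rmap = None
    else:
        parent_level = {15: 6, 6: 3}[level]
        parent_names = get_taxonomy(parent_level).names
        by_name = book["regroup"][key]
        rmap = {i: parent_names.index(by_name[n]) for i, n in enumerate(names)}
    return ClassTaxonomy(level=level, names=names, regroup_map=rmap)


def _lookup_table(src_level: int, dst_level: int) -> np.ndarray:
    """Integer lookup table composing regroup maps from src to dst level."""
    chain = {15: [15, 6, 3], 6: [6, 3], 3: [3]}[src_level]
    if dst_level not in chain:
        raise ValueError(f"cannot regroup level {src_level} to level {dst_level}")
    table = np.arange(get_taxonomy(src_level).n_classes)
    lev = src_level
    while lev != dst_level:
        tax = get_taxonomy(lev)
        step = np.array([tax.regroup_map[i] for i in range(tax.n_classes)])
        table = step[table]
        lev = {15: 6, 6: 3}[lev]
    return table


def regroup(mask: AnnotationMask, target_level: int) -> AnnotationMask:
    """Map an annotation mask to a coarser taxonomy level.

    Every pixel is mapped through the class table; pixel count is conserved
    and regrouping at the mask's own level is the identity.

    Raises
    ------
    ValueError
        If the mask contains a label outside its level's codebook (the
        offending code is named), or if the target level is finer than the
        mask's level.
    """
    if mask.level == target_level:
        return AnnotationMask(mask.labels.copy(), level=target_level)
    src = get_taxonomy(mask.level)
    bad = np.setdiff1d(np.unique(mask.labels), np.arange(src.n_classes))
    if bad.size:
        raise ValueError(
            f"unknown label code(s) {bad.tolist()} for taxonomy level {mask.level}"
        )
    table = _lookup_table(mask.level, target_level)
    return AnnotationMask(table[mask.labels], level=target_level)


def class_proportions(mask: AnnotationMask) -> dict[str, float]:
    """Fraction of pixels per class name; fractions sum to 1."""
    if mask.labels.size == 0:
        raise ValueError("empty annotation mask")
    tax = get_taxonomy(mask.level)
    counts = np.bincount(mask.labels.ravel(), minlength=tax.n_classes)
    frac = counts / counts.sum()
    return {name: float(f) for name, f in zip(tax.names, frac)}
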