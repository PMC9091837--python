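"""Transmission genetics of the hemiclone breeding design.

A hemiclone sire carries an intact haploid genome (X chromosome plus the two
major autosomes, co-segregating because males do not recombine) alongside a
standardized Y, a T(2;3) translocation marked with the dominant brown-eye
allele ``bw^D``, and a standardized 4th "dot" chromosome.  Crossed to
wild-type dams, the translocation heterozygosity means half of all zygotes
are aneuploid and die; the surviving sons split 1:1 into

* **PTGE-clones** — inherit the cloned wild-type autosomes (paternal direct
  *and* indirect genetic effects vary among sires), wild-type eyes;
* **PIGE-clones** — inherit the marked translocation (genotype standardized,
  so only paternal *indirect* effects vary), brown eyes.

Crossing a PIGE-clone onward gives **GPIGE-clones** in generation 2, probing
grandpaternal indirect effects.

This module encodes gamete formation, zygote viability, marker-based
classification, and the study's planned offspring tables (DesignTable).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeElement",
    "Karyotype",
    "Gamete",
    "Zygote",
    "CrossTally",
    "InvalidKaryotypeError",
    "InvalidCrossError",
    "sire_gametes",
    "dam_gametes",
    "fertilize",
    "run_cross",
    "build_design",
    "AMONG_POPULATIONS",
    "GPIGE_POPULATIONS",
    "DAM_POPULATION",
    "N_DGRP_LINES",
]

#: Source populations of the four cloned haploid genomes (among-population assay).
AMONG_POPULATIONS = ("LHm", "Congo", "Dahomey", "Z53")
#: Populations carried into the grand-offspring (GPIGE) assay.
GPIGE_POPULATIONS = ("Dahomey", "Z53")
#: All among-population dams come from this outbred population.
DAM_POPULATION = "Dahomey"
#: Number of DGRP hemiclone lines in the within-population assay.
N_DGRP_LINES = 38

BWD_MARKER = "bwD"

_SEX_KINDS = frozenset({"X", "Y", "attachedX"})
_AUTOSOME_KINDS = frozenset({"autosome_set", "translocation"})
_AUTOSOME_CONTENTS = (
    "balanced_wildtype",
    "balanced_translocation",
    "unbalanced_A",
    "unbalanced_B",
)


class InvalidKaryotypeError(ValueError):
    """Karyotype does not match the breeding design's requirements."""


class InvalidCrossError(ValueError):
    """Gamete combination impossible in the design (e.g. two Y-bearing gametes)."""


@dataclass(frozen=True)
class ChromosomeElement:
    """One segregating chromosomal unit.

    ``autosome_set`` stands for the co-segregating pair {chr2, chr3} (no male
    recombination); ``translocation`` is the fused T(2;3) element, which always
    carries the dominant ``bw^D`` marker.
    """

    kind: str
    origin: str = "standard"
    markers: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.kind not in _SEX_KINDS | _AUTOSOME_KINDS | {"dot4"}:
            raise InvalidKaryotypeError(f"unknown chromosome element kind {self.kind!r}")
        if self.kind == "translocation" and BWD_MARKER not in self.markers:
            object.__setattr__(self, "markers", self.markers | {BWD_MARKER})


def _translocation(origin: str = "standard") -> ChromosomeElement:
    return ChromosomeElement("translocation", origin, frozenset({BWD_MARKER}))


@dataclass(frozen=True)
class Karyotype:
    """A fly's chromosome complement at the design's level of abstraction."""

    sex_elements: tuple
    autosome_elements: tuple
    dot4: ChromosomeElement = ChromosomeElement("dot4", "standard")

    @property
    def is_male(self) -> bool:
        return any(e.kind == "Y" for e in self.sex_elements)

    @property
    def sex(self) -> str:
        return "male" if self.is_male else "female"

    def is_valid_hemiclone_sire(self) -> bool:
        """Exactly {X(clone), Y(standard)} and {autosome_set(clone), translocation}."""
        sex_kinds = sorted(e.kind for e in self.sex_elements)
        auto_kinds = sorted(e.kind for e in self.autosome_elements)
        return sex_kinds == ["X", "Y"] and auto_kinds == ["autosome_set", "translocation"]

    def is_valid_wildtype_dam(self) -> bool:
        sex_kinds = [e.kind for e in self.sex_elements]
        auto_kinds = [e.kind for e in self.autosome_elements]
        origins = {e.origin for e in self.sex_elements + self.autosome_elements}
        return sex_kinds == ["X", "X"] and auto_kinds == ["autosome_set", "autosome_set"] and len(origins) == 1

    @classmethod
    def hemiclone_sire(cls, clone_origin: str) -> "Karyotype":
        """A sire carrying the cloned haploid genome labelled ``clone_origin``."""
        return cls(
            sex_elements=(
                ChromosomeElement("X", clone_origin),
                ChromosomeElement("Y", "standard"),
            ),
            autosome_elements=(
                ChromosomeElement("autosome_set", clone_origin),
                _translocation("standard"),
            ),
        )

    @classmethod
    def wildtype_dam(cls, population: str) -> "Karyotype":
        return cls(
            sex_elements=(
                ChromosomeElement("X", f"pop:{population}"),
                ChromosomeElement("X", f"pop:{population}"),
            ),
            autosome_elements=(
                ChromosomeElement("autosome_set", f"pop:{population}"),
                ChromosomeElement("autosome_set", f"pop:{population}"),
            ),
        )


@dataclass(frozen=True)
class Gamete:
    """A gamete class: sex element plus one of four autosome segregation products.

    A translocation heterozygote produces the four autosome classes with equal
    probability: the intact wild-type set, the intact translocation, and two
    reciprocal unbalanced combinations (one intact element plus part of the
    other), represented abstractly since only their inviability matters.
    """

    sex_element: ChromosomeElement | None
    autosome_content: str
    origins: tuple = ()

    def __post_init__(self):
        if self.autosome_content not in _AUTOSOME_CONTENTS:
            raise InvalidKaryotypeError(f"unknown autosome content {self.autosome_content!r}")

    @property
    def balanced(self) -> bool:
        return self.autosome_content.startswith("balanced")

    @property
    def carries_bwD(self) -> bool:
        # both the intact translocation and its unbalanced fragments carry bw^D,
        # but only balanced classes ever reach a viable zygote
        return self.autosome_content in ("balanced_translocation", "unbalanced_A", "unbalanced_B")


@dataclass(frozen=True)
class Zygote:
    paternal: Gamete
    maternal: Gamete
    viable: bool
    sex: str
    clone_class: str
    eye_phenotype: str

    @property
    def genotype_signature(self) -> tuple:
        """Heritable nuclear composition, for asserting PIGE-clone identity.

        Origin labels of unbalanced (inviable) fragments are irrelevant and
        excluded; for viable zygotes the signature lists every transmitted
        element's (kind, origin).
        """
        elems = []
        for g in (self.maternal, self.paternal):
            if g.sex_element is not None:
                elems.append((g.sex_element.kind, g.sex_element.origin))
            if g.autosome_content == "balanced_wildtype":
                elems.append(("autosome_set", g.origins[0] if g.origins else "standard"))
            elif g.autosome_content == "balanced_translocation":
                elems.append(("translocation", "standard"))
        return tuple(sorted(elems))


def sire_gametes(sire: Karyotype) -> list[tuple[Gamete, float]]:
    """Enumerate the gamete classes of a translocation-heterozygous sire.

    Returns the 8 classes (2 sex elements x 4 autosome segregation products),
    each with probability 1/8.  Raises :class:`InvalidKaryotypeError` for a
    non-male or non-heterozygous karyotype.
    """
    if not sire.is_male:
        raise InvalidKaryotypeError("sire must be male (carry a Y element)")
    if not sire.is_valid_hemiclone_sire():
        raise InvalidKaryotypeError(
            "sire must be translocation-heterozygous with one cloned autosome set"
        )
    wild = next(e for e in sire.autosome_elements if e.kind == "autosome_set")
    out: list[tuple[Gamete, float]] = []
    for sex_el in sire.sex_elements:
        for content in _AUTOSOME_CONTENTS:
            origins = (wild.origin,) if content == "balanced_wildtype" else ("standard",)
            out.append((Gamete(sex_el, content, origins), 1.0 / 8.0))
    return out


def dam_gametes(dam: Karyotype) -> list[tuple[Gamete, float]]:
    """Gamete classes of a wild-type dam: a single balanced X-bearing class."""
    if not dam.is_valid_wildtype_dam():
        raise InvalidKaryotypeError("dam must be a wild-type XX female")
    x = dam.sex_elements[0]
    return [(Gamete(x, "balanced_wildtype", (dam.autosome_elements[0].origin,)), 1.0)]


def fertilize(paternal: Gamete, maternal: Gamete, generation: int = 1) -> Zygote:
    """Form a zygote and classify it.

    Viability requires balanced autosome content from both gametes (any
    unbalanced contribution is aneuploid-lethal).  Among viable sons of a
    generation-1 cross, the paternal balanced wild-type set defines a
    PTGE-clone and the paternal translocation a PIGE-clone (brown-eyed via
    ``bw^D``); in generation 2 the translocation class defines a GPIGE-clone.
    """
    pat_y = paternal.sex_element is not None and paternal.sex_element.kind == "Y"
    mat_y = maternal.sex_element is not None and maternal.sex_element.kind == "Y"
    if pat_y and mat_y:
        raise InvalidCrossError("two Y-bearing gametes cannot form a zygote in this design")

    viable = paternal.balanced and maternal.balanced
    sex = "male" if (pat_y or mat_y) else "female"

    if not viable:
        clone_class, eye = "inviable", "n/a"
    elif sex == "female":
        clone_class = "female"
        eye = "brown" if (paternal.carries_bwD or maternal.carries_bwD) else "wildtype"
    else:
        has_bwd = paternal.carries_bwD or maternal.carries_bwD
        eye = "brown" if has_bwd else "wildtype"
        if paternal.autosome_content == "balanced_translocation":
            clone_class = "GPIGE_clone" if generation >= 2 else "PIGE_clone"
        else:
            clone_class = "PTGE_clone"
    return Zygote(paternal, maternal, viable, sex, clone_class, eye)


@dataclass
class CrossTally:
    """Offspring counts from a simulated cross.

    ``counts`` maps (clone_class, sex, eye_phenotype) to egg counts;
    convenience accessors report viable males by clone class.
    """

    n_eggs: int
    counts: Counter
    zygotes: list | None = None

    @property
    def n_viable(self) -> int:
        return sum(n for (cc, _, _), n in self.counts.items() if cc != "inviable")

    def viable_males(self) -> dict:
        return {
            cc: n
            for (cc, sex, _), n in self.counts.items()
            if sex == "male" and cc != "inviable"
        }


def run_cross(
    sire: Karyotype,
    dam_label: str,
    n_eggs: int,
    seed: int,
    generation: int = 1,
    return_zygotes: bool = False,
) -> CrossTally:
    """Multinomially sample ``n_eggs`` zygotes from a sire x wild-type-dam cross.

    Sampling is over the analytic zygote-class distribution (sire gamete
    classes x the dam's single balanced class), deterministic under ``seed``.
    """
    if n_eggs < 0:
        raise ValueError("n_eggs must be non-negative")
    dam = Karyotype.wildtype_dam(dam_label)
    (mat, _), = dam_gametes(dam)
    classes = [(fertilize(pat, mat, generation=generation), p) for pat, p in sire_gametes(sire)]
    probs = np.array([p for _, p in classes])
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_eggs, probs) if n_eggs > 0 else np.zeros(len(classes), dtype=int)
    counts: Counter = Counter()
    for (z, _), n in zip(classes, draws):
        if n:
            counts[(z.clone_class, z.sex, z.eye_phenotype)] += int(n)
    zygotes = None
    if return_zygotes:
        zygotes = [z for (z, _), n in zip(classes, draws) for _ in range(int(n))]
    return CrossTally(n_eggs=n_eggs, counts=counts, zygotes=zygotes)


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["group", "clone_type", "generation", "vial_id", "block", "slot_id"]


def _rows(group, clone_type, generation, n_vials, per_vial, block, prefix, start_vial=0):
    recs = []
    for v in range(n_vials):
        vial_id = f"{prefix}_{group}_{clone_type}_v{start_vial + v + 1:02d}"
        for s in range(per_vial):
            recs.append((group, clone_type, generation, vial_id, block, f"{vial_id}_s{s + 1:02d}"))
    return recs


def build_design(study: str) -> pd.DataFrame:
    """Planned offspring table for one of the study's three assays.

    ``among_population``: 4 populations x (10 vials x 50 PTGE-clones +
    20 vials x 50 PIGE-clones).  ``gpige``: 2 populations x 20 vials x 50
    GPIGE-clones (generation 2).  ``within_population``: 38 DGRP lines x
    8 vials x 50 PIGE-clones, two vials per line in each of 4 blocks.
    """
    recs: list = []
    if study == "among_population":
        for pop in AMONG_POPULATIONS:
            recs += _rows(pop, "PTGE_clone", 1, 10, 50, "", "AP")
            recs += _rows(pop, "PIGE_clone", 1, 20, 50, "", "AP")
    elif study == "gpige":
        for pop in GPIGE_POPULATIONS:
            recs += _rows(pop, "GPIGE_clone", 2, 20, 50, "", "GP")
    elif study == "within_population":
        for line in range(1, N_DGRP_LINES + 1):
            group = f"line_{line:02d}"
            vial = 0
            for block in ("B1", "B2", "B3", "B4"):
                recs += _rows(group, "PIGE_clone", 1, 2, 50, block, "WP", start_vial=vial)
                vial += 2
    else:
        raise ValueError(
            f"unknown study {study!r}; expected among_population, within_population or gpige"
        )
    return pd.DataFrame.from_records(recs, columns=DESIGN_COLUMNS)
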