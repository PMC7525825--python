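"""Cross designs and composite-effect coefficient conventions.

A line-cross experiment derives a set of cohorts (parental lines, F1
hybrids, backcrosses) from two divergent parental lines, P1 (low) and P2
(high).  Each cohort has a known expected genomic composition, which fixes
the coefficient with which every composite genetic effect (autosomal
additive, X dominance, cytotype, maternal, and their pairwise epistatic
products) can contribute to that cohort's mean phenotype.

Coefficient scale conventions used throughout (all configurable at the
C-matrix level by supplying a user matrix):

* additive effects run on [-1, +1] with P2 positive,
* dominance effects run on [0, 1] (expected heterozygosity),
* cytotype is +1 for an unbroken P2 dam line and -1 otherwise,
* maternal effects take the dam line's additive/dominance coefficient,
* X and Y coefficients assume a male-heterogametic (XY) system; the
  ``pooled`` sex mode averages female and male expectations 1:1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LINE_CODES",
    "SIMPLE_EFFECTS",
    "LinePedigree",
    "CompositeEffect",
    "standard_pedigree",
    "simple_effect_coefficient",
    "default_effect_set",
]

#: The eight cohorts of the standard design, in canonical order.
LINE_CODES = ("P1", "P2", "F1", "rF1", "BC1", "rBC1", "BC2", "rBC2")

#: Simple (non-epistatic) composite effects: autosomal additive and
#: dominance, X additive and dominance, Y additive, cytotype, and
#: additive/dominance maternal effects.
SIMPLE_EFFECTS = ("Aa", "Ad", "Xa", "Xd", "Ya", "Ca", "Ma", "Md")

#: Default cross directions, ``line: (dam, sire)``.
DEFAULT_CROSSES = {
    "F1": ("P1", "P2"),
    "rF1": ("P2", "P1"),
    "BC1": ("F1", "P1"),
    "rBC1": ("rF1", "P1"),
    "BC2": ("F1", "P2"),
    "rBC2": ("rF1", "P2"),
}


@dataclass(frozen=True)
class LinePedigree:
    """Expected genomic composition of one cohort.

    ``x_p2_female`` is the expected fraction of a female's two X copies
    that are P2-derived, ``x_p2_male`` the probability that a male's
    single X is P2-derived, and ``x_het_female`` the probability that a
    female carries one P1- and one P2-derived X.
    """

    line_code: str
    dam_code: str
    sire_code: str
    p2_autosome_fraction: float
    expected_heterozygosity: float
    maternal_lineage: str  # "P1" or "P2": unbroken dam line
    patriline: str  # "P1" or "P2": unbroken sire line (Y source)
    x_p2_female: float
    x_p2_male: float
    x_het_female: float
    dam_p2_autosome_fraction: float
    dam_expected_heterozygosity: float


@dataclass(frozen=True)
class CompositeEffect:
    """A simple effect or a digenic (pairwise) epistatic product."""

    effect_id: str
    category: str  # "simple" or "epistatic"
    factor_ids: tuple[str, ...]

    def __post_init__(self):
        n = len(self.factor_ids)
        if self.category == "simple" and n != 1:
            raise ValueError(f"simple effect {self.effect_id!r} needs 1 factor, got {n}")
        if self.category == "epistatic" and n != 2:
            raise ValueError(f"epistatic effect {self.effect_id!r} needs 2 factors, got {n}")

    @classmethod
    def from_token(cls, token: str) -> "CompositeEffect":
        """Classify a token: a known simple effect, a concatenation of two
        simple effects (epistatic), or otherwise a user-defined simple column."""
        if token in SIMPLE_EFFECTS:
            return cls(token, "simple", (token,))
        if len(token) == 4 and token[:2] in SIMPLE_EFFECTS and token[2:] in SIMPLE_EFFECTS:
            return cls(token, "epistatic", (token[:2], token[2:]))
        return cls(token, "simple", (token,))


def _base_line(code: str) -> LinePedigree:
    p2 = 1.0 if code == "P2" else 0.0
    return LinePedigree(
        line_code=code, dam_code=code, sire_code=code,
        p2_autosome_fraction=p2, expected_heterozygosity=0.0,
        maternal_lineage=code, patriline=code,
        x_p2_female=p2, x_p2_male=p2, x_het_female=0.0,
        dam_p2_autosome_fraction=p2, dam_expected_heterozygosity=0.0,
    )


def _derive(code: str, dam: LinePedigree, sire: LinePedigree) -> LinePedigree:
    # Transmission probabilities: a parent passes a P2-derived autosomal
    # allele with probability equal to its own P2 genome fraction (loci
    # unlinked and exchangeable under the fixed-difference model).
    pd_, ps = dam.p2_autosome_fraction, sire.p2_autosome_fraction
    # Females get one X from each parent; males get a random maternal X.
    xf = (dam.x_p2_female + sire.x_p2_male) / 2.0
    return LinePedigree(
        line_code=code, dam_code=dam.line_code, sire_code=sire.line_code,
        p2_autosome_fraction=(pd_ + ps) / 2.0,
        expected_heterozygosity=pd_ * (1 - ps) + ps * (1 - pd_),
        maternal_lineage=dam.maternal_lineage,
        patriline=sire.patriline,
        x_p2_female=xf,
        x_p2_male=dam.x_p2_female,
        x_het_female=dam.x_p2_female * (1 - sire.x_p2_male)
        + (1 - dam.x_p2_female) * sire.x_p2_male,
        dam_p2_autosome_fraction=dam.p2_autosome_fraction,
        dam_expected_heterozygosity=dam.expected_heterozygosity,
    )


def standard_pedigree(crosses: dict[str, tuple[str, str]] | None = None) -> list[LinePedigree]:
    """Return the 8 cohorts of the standard design.

    Parameters
    ----------
    crosses
        Optional override of cross directions, mapping a derived line code
        to ``(dam_line, sire_line)``.  Defaults to :data:`DEFAULT_CROSSES`
        (e.g. F1 has a P1 dam and a P2 sire).  Dam lines must be defined
        before the lines derived from them.
    """
    plan = dict(DEFAULT_CROSSES)
    if crosses:
        unknown = set(crosses) - set(plan)
        if unknown:
            raise ValueError(f"unknown derived line(s): {sorted(unknown)}")
        plan.update(crosses)
    table: dict[str, LinePedigree] = {"P1": _base_line("P1"), "P2": _base_line("P2")}
    for code in ("F1", "rF1", "BC1", "rBC1", "BC2", "rBC2"):
        dam, sire = plan[code]
        for parent in (dam, sire):
            if parent not in table:
                raise ValueError(f"{code}: parent line {parent!r} not defined yet")
        table[code] = _derive(code, table[dam], table[sire])
    return [table[c] for c in LINE_CODES]


def simple_effect_coefficient(pedigree: LinePedigree, effect_id: str,
                              sex_mode: str = "pooled") -> float:
    """C-matrix coefficient of one simple effect for one cohort.

    ``sex_mode`` is ``"pooled"`` (females and males 1:1), ``"female"`` or
    ``"male"``; it only changes the sex-linked effects (Xa, Xd, Ya).
    """
    if sex_mode not in ("pooled", "female", "male"):
        raise ValueError(f"sex_mode must be pooled/female/male, got {sex_mode!r}")
    p = pedigree
    if effect_id == "Aa":
        return 2.0 * p.p2_autosome_fraction - 1.0
    if effect_id == "Ad":
        return p.expected_heterozygosity
    if effect_id == "Ca":
        return 1.0 if p.maternal_lineage == "P2" else -1.0
    if effect_id == "Ma":
        return 2.0 * p.dam_p2_autosome_fraction - 1.0
    if effect_id == "Md":
        return p.dam_expected_heterozygosity
    if effect_id == "Xa":
        female = 2.0 * p.x_p2_female - 1.0
        male = 2.0 * p.x_p2_male - 1.0
    elif effect_id == "Xd":
        female = p.x_het_female
        male = 0.0  # hemizygous: no X dominance in males
    elif effect_id == "Ya":
        female = 0.0  # no Y in females
        male = 1.0 if p.patriline == "P2" else -1.0
    else:
        raise ValueError(
            f"unknown simple effect {effect_id!r}; valid tokens: {', '.join(SIMPLE_EFFECTS)}")
    if sex_mode == "female":
        return female
    if sex_mode == "male":
        return male
    return (female + male) / 2.0


def default_effect_set(pedigrees: list[LinePedigree] | None = None,
                       sex_mode: str = "pooled",
                       n_epistatic: int | None = 19,
                       simple_tokens: tuple[str, ...] = SIMPLE_EFFECTS) -> list[CompositeEffect]:
    """The default 27-effect set: 8 simple effects plus 19 digenic products.

    Epistatic candidates are all products of simple-effect pairs (with
    replacement) in canonical order (Aa, Ad, Xa, Xd, Ya, Ca, Ma, Md).  A
    candidate column is skipped when, across the supplied cohorts, it is
    identically zero, constant (indistinguishable from the mean term), or
    an exact duplicate of a column already in the set; the first
    ``n_epistatic`` admissible products are kept (all of them when
    ``n_epistatic`` is None).  With the standard 8-cohort pedigree and the
    full simple set this yields AaAa .. XaCa.

    ``simple_tokens`` restricts the basis, e.g. ``("Aa", "Ad", "Ca",
    "Ma", "Md")`` for a system with no sex chromosomes.
    """
    if pedigrees is None:
        pedigrees = standard_pedigree()
    unknown = set(simple_tokens) - set(SIMPLE_EFFECTS)
    if unknown:
        raise ValueError(f"unknown simple effect(s): {sorted(unknown)}")
    simple_cols = {
        e: np.array([simple_effect_coefficient(p, e, sex_mode) for p in pedigrees])
        for e in simple_tokens
    }
    effects = [CompositeEffect(e, "simple", (e,)) for e in simple_tokens]
    kept_cols = [np.ones(len(pedigrees))] + list(simple_cols.values())
    for i, j in itertools.combinations_with_replacement(range(len(simple_tokens)), 2):
        n_epi = sum(e.category == "epistatic" for e in effects)
        if n_epistatic is not None and n_epi >= n_epistatic:
            break
        fa, fb = simple_tokens[i], simple_tokens[j]
        col = simple_cols[fa] * simple_cols[fb]
        if np.all(col == 0) or np.ptp(col) == 0:
            continue
        if any(np.array_equal(col, kc) for kc in kept_cols):
            continue
        effects.append(CompositeEffect(fa + fb, "epistatic", (fa, fb)))
        kept_cols.append(col)
    return effects


#: Simple effects expressible by a genome of autosomes plus a maternally
#: inherited cytotype (no sex chromosomes), as in the forward simulator.
AUTOCYTO_SIMPLE = ("Aa", "Ad", "Ca", "Ma", "Md")


def autocyto_effect_set(pedigrees: list[LinePedigree] | None = None,
                        sex_mode: str = "pooled") -> list[CompositeEffect]:
    """Effect set for an autosome+cytotype genetic system: 5 simple
    effects plus every admissible digenic product (11 with the standard
    pedigree, 16 effects in total)."""
    return default_effect_set(pedigrees, sex_mode, n_epistatic=None,
                              simple_tokens=AUTOCYTO_SIMPLE)
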