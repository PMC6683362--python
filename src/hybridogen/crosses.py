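"""Deterministic gamete and cross models for hybridogenetic systems.

Water-frog hybrids (*P.* kl. *esculentus*, genomes LR) typically exclude
one parental genome from the germline and transmit the other clonally.
Sex is determined by an XY system in which the Y only occurs on the
lessonae-derived (L) genome: primary hybridizations involve LL males and
RR females, so the R genome is strictly X-linked and hybrid males are
LyRx while hybrid females are LxRx.  This module tracks genome copies
with their sex chromosomes through configurable gametogenesis rules and
enumerates exact offspring distributions for single crosses and for
deterministic generation-to-generation recursions.

Presets cover the classic L-E system (hybrids transmit clonal R gametes
and backcross to *P. lessonae*), its mirror R-E system, a mixed-ploidy
all-hybrid E-E system maintained through triploids, and a hypothetical
diploid all-hybrid system maintained by "hybrid amphigamy", where both
sexes produce L- and R-carrying gametes.  Homotypic offspring (LL or RR
assembled from hemiclones) carry the hybridogenetic load and default to
zero viability in the all-hybrid presets.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping

from .errors import ConfigurationError, ModelError

__all__ = [
    "GenomeCopy",
    "FrogGenotype",
    "Gamete",
    "GameteRule",
    "Viability",
    "CrossResult",
    "SystemPreset",
    "gamete_distribution",
    "cross",
    "cross_from_preset",
    "system_preset",
    "generation_step",
    "PRESETS",
]

log = logging.getLogger(__name__)

_TOL = 1e-9


@dataclasses.dataclass(frozen=True, order=True)
class GenomeCopy:
    """One haploid genome copy: lineage (L or R) plus sex chromosome."""

    lineage: str  # "L" or "R"
    sex_chrom: str  # "X" or "Y"

    def __post_init__(self) -> None:
        if self.lineage not in ("L", "R"):
            raise ModelError(f"lineage must be L or R, got {self.lineage!r}")
        if self.sex_chrom not in ("X", "Y"):
            raise ModelError(f"sex chromosome must be X or Y, got {self.sex_chrom!r}")

    @property
    def label(self) -> str:
        return f"{self.lineage}{self.sex_chrom.lower()}"


LX = GenomeCopy("L", "X")
LY = GenomeCopy("L", "Y")
RX = GenomeCopy("R", "X")

Gamete = tuple[GenomeCopy, ...]


def _canon(copies) -> tuple[GenomeCopy, ...]:
    return tuple(sorted(copies))


@dataclasses.dataclass(frozen=True)
class FrogGenotype:
    """A diploid or triploid genome composition with sex chromosomes.

    Sex is a pure function of the copies: male iff any Y is present.
    Under the default model an R copy never carries a Y (the R genome is
    strictly X-linked); pass ``allow_r_y=True`` to relax this for
    hypothetical scenarios (the relaxation is logged).
    """

    copies: tuple[GenomeCopy, ...]

    def __init__(self, copies, allow_r_y: bool = False) -> None:
        copies = _canon(copies)
        if len(copies) not in (2, 3):
            raise ModelError(f"genotype must have 2 or 3 genome copies, got {len(copies)}")
        for c in copies:
            if c.lineage == "R" and c.sex_chrom == "Y" and not allow_r_y:
                raise ModelError(
                    "R genome copies are strictly X-linked under the default model; "
                    "pass allow_r_y=True to relax"
                )
            if c.lineage == "R" and c.sex_chrom == "Y":
                log.warning("allowing Y-bearing R copy %s", c.label)
        object.__setattr__(self, "copies", copies)

    @classmethod
    def parse(cls, label: str, allow_r_y: bool = False) -> "FrogGenotype":
        """Parse labels like ``LxRx`` or ``LLRxxy`` — pairs of
        (lineage, chromosome) characters, e.g. ``LyRx``, ``LxLyRx``."""
        if len(label) % 2 != 0:
            raise ModelError(f"cannot parse genotype label {label!r}")
        copies = []
        for i in range(0, len(label), 2):
            copies.append(GenomeCopy(label[i].upper(), label[i + 1].upper()))
        return cls(copies, allow_r_y=allow_r_y)

    @property
    def label(self) -> str:
        return "".join(c.label for c in self.copies)

    @property
    def composition(self) -> str:
        """Lineage multiset string: LL, LR, RR, LLR or LRR."""
        return "".join(sorted(c.lineage for c in self.copies))

    @property
    def sex(self) -> str:
        return "M" if any(c.sex_chrom == "Y" for c in self.copies) else "F"

    @property
    def ploidy(self) -> int:
        return len(self.copies)

    @property
    def is_hybrid(self) -> bool:
        lineages = {c.lineage for c in self.copies}
        return lineages == {"L", "R"}

    def __repr__(self) -> str:
        return f"FrogGenotype({self.label})"


# ---------------------------------------------------------------------------
# Gametogenesis
# ---------------------------------------------------------------------------

ELIMINATE_L = "ELIMINATE_L"
ELIMINATE_R = "ELIMINATE_R"
AMPHI = "AMPHI"
DIPLOID_LR = "DIPLOID_LR"
MENDELIAN = "MENDELIAN"
TRIPLOID_RULE = "TRIPLOID_RULE"

#: triploid gametogenesis table: composition -> ((gamete lineage string, prob), ...)
TriploidTable = Mapping[str, tuple[tuple[str, float], ...]]


@dataclasses.dataclass(frozen=True)
class GameteRule:
    """A gametogenesis mode.

    ``ELIMINATE_L`` / ``ELIMINATE_R`` drop every copy of that lineage
    from the germline and segregate the remainder (clonal transmission
    for a single remaining copy, Mendelian 1/2-1/2 for two).  ``AMPHI``
    transmits the L copy of a diploid hybrid with probability ``q`` and
    the R copy with 1-q ("hybrid amphigamy").  ``DIPLOID_LR`` emits an
    unreduced LR gamete.  ``MENDELIAN`` segregates a diploid's two
    copies.  ``TRIPLOID_RULE`` consults a per-composition table of
    (gamete lineage string, probability) entries, e.g. LLR -> haploid
    recombined L and/or unreduced LL.
    """

    mode: str
    q: float = 0.5
    triploid_table: TriploidTable | None = None

    def __post_init__(self) -> None:
        if self.mode not in (ELIMINATE_L, ELIMINATE_R, AMPHI, DIPLOID_LR, MENDELIAN, TRIPLOID_RULE):
            raise ConfigurationError(f"unknown gametogenesis mode {self.mode!r}")
        if not (0.0 <= self.q <= 1.0):
            raise ConfigurationError("q must lie in [0, 1]")
        if self.mode == TRIPLOID_RULE:
            if not self.triploid_table:
                raise ConfigurationError("TRIPLOID_RULE needs a triploid_table")
            for comp, entries in self.triploid_table.items():
                total = sum(p for _, p in entries)
                if abs(total - 1.0) > _TOL:
                    raise ConfigurationError(
                        f"triploid table for {comp} sums to {total}, not 1"
                    )


def _merge(dist: dict[Gamete, float], gamete, prob: float) -> None:
    if prob <= 0:
        return
    key = _canon(gamete)
    dist[key] = dist.get(key, 0.0) + prob


def _segregate(copies: tuple[GenomeCopy, ...]) -> dict[Gamete, float]:
    """Haploid gametes from the remaining germline copies: clonal for
    one copy, Mendelian for two."""
    dist: dict[Gamete, float] = {}
    if len(copies) == 1:
        _merge(dist, (copies[0],), 1.0)
    elif len(copies) == 2:
        for c in copies:
            _merge(dist, (c,), 0.5)
    else:
        raise ModelError(f"cannot segregate {len(copies)} germline copies")
    return dist


def _lineage_choices(g: FrogGenotype, lineage_str: str) -> dict[Gamete, float]:
    """All ways to draw the multiset of lineages in ``lineage_str`` from
    g's copies, uniformly over distinct copy combinations."""
    need: dict[str, int] = {}
    for ch in lineage_str:
        need[ch] = need.get(ch, 0) + 1
    pools = {
        lin: [c for c in g.copies if c.lineage == lin] for lin in need
    }
    for lin, k in need.items():
        if len(pools[lin]) < k:
            raise ModelError(
                f"gamete spec {lineage_str!r} not drawable from genotype {g.label}"
            )
    dist: dict[Gamete, float] = {}
    per_lineage = []
    for lin, k in sorted(need.items()):
        combos = list(itertools.combinations(pools[lin], k))
        per_lineage.append(combos)
    all_combos = list(itertools.product(*per_lineage))
    p = 1.0 / len(all_combos)
    for combo in all_combos:
        gamete = tuple(itertools.chain.from_iterable(combo))
        _merge(dist, gamete, p)
    return dist


def gamete_distribution(g: FrogGenotype, rule: GameteRule) -> dict[Gamete, float]:
    """Exact gamete distribution of genotype ``g`` under ``rule``.

    Raises :class:`ModelError` when the rule cannot act on the genotype
    (e.g. ELIMINATE_L on an LL frog, which has no R genome to transmit).
    """
    comp = g.composition
    if rule.mode in (ELIMINATE_L, ELIMINATE_R):
        drop = "L" if rule.mode == ELIMINATE_L else "R"
        kept = tuple(c for c in g.copies if c.lineage != drop)
        if len(kept) == len(g.copies) or not kept:
            raise ModelError(f"rule {rule.mode} is not applicable to genotype {g.label}")
        dist = _segregate(kept)
    elif rule.mode == AMPHI:
        if comp != "LR":
            raise ModelError(f"AMPHI requires a diploid LR hybrid, got {g.label}")
        l_copy = next(c for c in g.copies if c.lineage == "L")
        r_copy = next(c for c in g.copies if c.lineage == "R")
        dist = {}
        _merge(dist, (l_copy,), rule.q)
        _merge(dist, (r_copy,), 1.0 - rule.q)
    elif rule.mode == DIPLOID_LR:
        if comp != "LR":
            raise ModelError(f"DIPLOID_LR requires a diploid LR hybrid, got {g.label}")
        dist = {_canon(g.copies): 1.0}
    elif rule.mode == MENDELIAN:
        if g.ploidy != 2:
            raise ModelError(f"MENDELIAN segregation requires a diploid, got {g.label}")
        dist = _segregate(g.copies)
    elif rule.mode == TRIPLOID_RULE:
        entries = (rule.triploid_table or {}).get(comp)
        if entries is None:
            raise ModelError(f"no triploid-table entry for composition {comp}")
        dist = {}
        for lineage_str, p in entries:
            for gamete, sub_p in _lineage_choices(g, lineage_str).items():
                _merge(dist, gamete, p * sub_p)
    else:  # pragma: no cover - guarded by GameteRule validation
        raise ConfigurationError(rule.mode)
    total = sum(dist.values())
    if abs(total - 1.0) > _TOL:
        raise ModelError(f"gamete distribution sums to {total}, not 1")
    return dist


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Viability:
    """Per-class relative viability weights.

    Homotypic LL/RR offspring assembled from hemiclonal genomes suffer
    the hybridogenetic load; all-hybrid presets default them to 0.
    Small positive values model the rare surviving adults (like
    hemiclonal RR females observed in the field).
    """

    w_ll: float = 1.0
    w_rr: float = 1.0
    w_hybrid: float = 1.0

    def weight(self, g: FrogGenotype) -> float:
        lineages = {c.lineage for c in g.copies}
        if lineages == {"L"}:
            return self.w_ll
        if lineages == {"R"}:
            return self.w_rr
        return self.w_hybrid


@dataclasses.dataclass
class CrossResult:
    """Offspring distribution of one mother x father cross.

    ``pre`` sums to 1; ``post`` applies the viability weights and
    renormalizes (empty when no class survives).
    """

    mother: FrogGenotype
    father: FrogGenotype
    pre: dict[FrogGenotype, float]
    post: dict[FrogGenotype, float]
    viability: Viability


def cross(
    mother: FrogGenotype,
    mother_rule: GameteRule,
    father: FrogGenotype,
    father_rule: GameteRule,
    viability: Viability = Viability(),
    allow_r_y: bool = False,
    invalid_union: str = "error",
) -> CrossResult:
    """Exact offspring distribution as the product of the two gamete
    distributions, with gametes unioned into offspring genotypes.

    A union outside ploidy 2-3 (e.g. a diploid egg meeting a diploid
    sperm) raises :class:`ModelError` by default; with
    ``invalid_union="drop"`` its mass is treated as inviable and the
    remaining pre-viability distribution is renormalized.
    """
    if mother.sex != "F":
        raise ModelError(f"mother {mother.label} is not female")
    if father.sex != "M":
        raise ModelError(f"father {father.label} is not male")
    eggs = gamete_distribution(mother, mother_rule)
    sperm = gamete_distribution(father, father_rule)
    pre: dict[FrogGenotype, float] = {}
    for (egg, pe), (sp, ps) in itertools.product(eggs.items(), sperm.items()):
        copies = egg + sp
        if len(copies) not in (2, 3):
            if invalid_union == "drop":
                continue
            raise ModelError(
                f"gamete union of {egg} and {sp} has {len(copies)} copies; "
                "not a diploid or triploid offspring"
            )
        child = FrogGenotype(copies, allow_r_y=allow_r_y)
        pre[child] = pre.get(child, 0.0) + pe * ps
    total = sum(pre.values())
    if total <= 0:
        raise ModelError("no viable-ploidy gamete unions in this cross")
    if invalid_union == "drop" and abs(total - 1.0) > _TOL:
        pre = {g: p / total for g, p in pre.items()}
    elif abs(total - 1.0) > _TOL:
        raise ModelError(f"offspring distribution sums to {total}")
    post_raw = {g: p * viability.weight(g) for g, p in pre.items()}
    surviving = sum(post_raw.values())
    post = (
        {g: p / surviving for g, p in post_raw.items() if p > 0}
        if surviving > 0
        else {}
    )
    return CrossResult(mother, father, pre, post, viability)


# ---------------------------------------------------------------------------
# System presets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SystemPreset:
    """Gametogenesis rules per (composition, sex) plus default viabilities."""

    name: str
    rules: dict[str, GameteRule | dict[str, GameteRule]]
    viability: Viability

    def rule_for(self, g: FrogGenotype) -> GameteRule:
        entry = self.rules.get(g.composition)
        if entry is None:
            raise ModelError(
                f"preset {self.name} has no rule for composition {g.composition}"
            )
        if isinstance(entry, dict):
            return entry[g.sex]
        return entry


def _mendelian() -> GameteRule:
    return GameteRule(MENDELIAN)


PRESET_NAMES = ("L_E", "R_E", "E_E_TRIPLOID", "E_E_DIPLOID_AMPHIGAMY")


def system_preset(name: str) -> SystemPreset:
    """A fully specified rule set for a named hybridogenetic system.

    * ``L_E``: hybrids of both sexes eliminate L and transmit clonal R
      gametes; they backcross to sexual *P. lessonae*.  RR offspring of
      inter-hybrid crosses are unviable (w_RR = 0); the sexual parental
      LL is fully viable.
    * ``R_E``: the mirror system; hybrids transmit L, LL offspring
      carry the load.
    * ``E_E_TRIPLOID``: mixed-ploidy all-hybrid system — LR females lay
      unreduced LR eggs, LR males produce R sperm, LLR frogs produce
      recombined haploid L gametes (males also unreduced LL sperm), LRR
      frogs produce haploid R gametes; homotypic offspring unviable.
    * ``E_E_DIPLOID_AMPHIGAMY``: the hypothetical diploid all-hybrid
      system — both sexes transmit L or R gametes with probability q =
      0.5 each; homotypic offspring unviable by default.
    """
    if name == "L_E":
        return SystemPreset(
            name,
            rules={
                "LR": GameteRule(ELIMINATE_L),
                "LL": _mendelian(),
                "RR": _mendelian(),
            },
            viability=Viability(w_ll=1.0, w_rr=0.0, w_hybrid=1.0),
        )
    if name == "R_E":
        return SystemPreset(
            name,
            rules={
                "LR": GameteRule(ELIMINATE_R),
                "LL": _mendelian(),
                "RR": _mendelian(),
            },
            viability=Viability(w_ll=0.0, w_rr=1.0, w_hybrid=1.0),
        )
    if name == "E_E_TRIPLOID":
        triploid_m = GameteRule(
            TRIPLOID_RULE,
            triploid_table={"LLR": (("L", 0.5), ("LL", 0.5)), "LRR": (("R", 1.0),)},
        )
        triploid_f = GameteRule(
            TRIPLOID_RULE,
            triploid_table={"LLR": (("L", 1.0),), "LRR": (("R", 1.0),)},
        )
        return SystemPreset(
            name,
            rules={
                "LR": {"F": GameteRule(DIPLOID_LR), "M": GameteRule(ELIMINATE_L)},
                "LLR": {"F": triploid_f, "M": triploid_m},
                "LRR": {"F": triploid_f, "M": triploid_m},
                "LL": _mendelian(),
                "RR": _mendelian(),
            },
            viability=Viability(w_ll=0.0, w_rr=0.0, w_hybrid=1.0),
        )
    if name == "E_E_DIPLOID_AMPHIGAMY":
        return SystemPreset(
            name,
            rules={
                "LR": GameteRule(AMPHI, q=0.5),
                "LL": _mendelian(),
                "RR": _mendelian(),
            },
            viability=Viability(w_ll=0.0, w_rr=0.0, w_hybrid=1.0),
        )
    raise ConfigurationError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


PRESETS = PRESET_NAMES


def cross_from_preset(
    preset: SystemPreset,
    mother: FrogGenotype,
    father: FrogGenotype,
    invalid_union: str = "error",
) -> CrossResult:
    return cross(
        mother,
        preset.rule_for(mother),
        father,
        preset.rule_for(father),
        viability=preset.viability,
        invalid_union=invalid_union,
    )


def generation_step(
    freqs: Mapping[FrogGenotype, float], preset: SystemPreset
) -> dict[FrogGenotype, float]:
    """One generation of deterministic random mating within sex.

    Mothers (females) and fathers (males) are taken from ``freqs``,
    renormalized within sex; the offspring pool sums the post-viability
    distributions of every mother x father pair.  An extension beyond
    single-cross statements: no ecology, just genotype-frequency
    recursion.
    """
    females = {g: f for g, f in freqs.items() if g.sex == "F" and f > 0}
    males = {g: f for g, f in freqs.items() if g.sex == "M" and f > 0}
    if not females or not males:
        raise ModelError("generation_step needs both sexes at positive frequency")
    fsum = sum(females.values())
    msum = sum(males.values())
    out: dict[FrogGenotype, float] = {}
    for (mg, mf), (fg, ff) in itertools.product(females.items(), males.items()):
        result = cross_from_preset(preset, mg, fg, invalid_union="drop")
        w = (mf / fsum) * (ff / msum)
        for child, p in result.post.items():
            out[child] = out.get(child, 0.0) + w * p
    total = sum(out.values())
    return {g: p / total for g, p in out.items()} if total > 0 else {}


def cross_table(result: CrossResult) -> "pd.DataFrame":
    """Offspring distribution as a tidy table (genotype, composition,
    sex, pre- and post-viability probability)."""
    import pandas as pd

    genotypes = sorted(result.pre, key=lambda g: g.label)
    rows = [
        (
            g.label,
            g.composition,
            g.sex,
            result.pre[g],
            result.post.get(g, 0.0),
        )
        for g in genotypes
    ]
    return pd.DataFrame(
        rows, columns=["genotype", "composition", "sex", "pre_viability_p", "post_viability_p"]
    )
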