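"""Concordance between 16S rRNA taxonomy calls and MALDI-TOF identifications.

Each isolate's pair of calls is assigned to exactly one category:

* ``species_concordant`` — both methods name the same species and the
  MALDI log score passes the identification threshold;
* ``maldi_confident_discordant`` — the species names differ but the MALDI
  score passes the threshold against a characterized type-strain entry, so
  the spectral call is taken as the accurate one;
* ``potentially_novel`` — the MALDI consensus is unidentified (score below
  the threshold), even in the presence of reference spectra from closely
  related species;
* ``taxgroup_unresolved`` — the 16S call lands inside a registered
  taxonomic group (a set of species with near-identical 16S sequences) and
  the library lacks type-strain spectra for competing group members, so the
  discordance cannot be adjudicated;
* ``genus_only`` — agreement only at genus granularity.

A genus-level mismatch between the two methods is treated as a data
inconsistency and raises.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ParsedName",
    "TaxGroupRegistry",
    "ConcordanceRecord",
    "CATEGORIES",
    "parse_entry_name",
    "species_match",
    "categorize",
    "tabulate",
    "default_registry",
]

CATEGORIES = (
    "species_concordant",
    "maldi_confident_discordant",
    "potentially_novel",
    "taxgroup_unresolved",
    "genus_only",
)

DEFAULT_THRESHOLD = 2.2


class ConcordanceError(ValueError):
    """Raised on a genus-level mismatch between the two methods."""


@dataclass(frozen=True)
class ParsedName:
    genus: str
    species: str
    strain: str = ""
    is_type_strain: bool = False

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}".strip()


def parse_entry_name(name: str) -> ParsedName:
    """Parse names like ``Bacillus safensis_FO36b^T`` or ``B. pumilus``.

    Tokens are split on whitespace and underscores; the first token is the
    genus (possibly abbreviated, e.g. ``B.``), the second the species
    epithet, the remainder the strain designation.  A trailing ``^T`` (or
    ``(T)``) marks a type strain.
    """
    raw = name.strip()
    is_type = bool(re.search(r"\^T$|\(T\)$|\s+T$", raw))
    cleaned = re.sub(r"\^T$|\(T\)$", "", raw).strip()
    tokens = [t for t in re.split(r"[\s_]+", cleaned) if t]
    if not tokens:
        raise ValueError(f"cannot parse taxon name {name!r}")
    genus = tokens[0]
    species = tokens[1] if len(tokens) > 1 else ""
    strain = " ".join(tokens[2:])
    return ParsedName(genus=genus, species=species.lower(), strain=strain,
                      is_type_strain=is_type)


def _genus_match(a: str, b: str) -> bool:
    a, b = a.rstrip("."), b.rstrip(".")
    if not a or not b:
        return False
    if len(a) == 1 or len(b) == 1:  # abbreviated genus: match on initial
        return a[0].upper() == b[0].upper()
    return a.lower() == b.lower()


def species_match(a: str | ParsedName, b: str | ParsedName) -> bool:
    """True when two names refer to the same species (genus may be abbreviated)."""
    pa = a if isinstance(a, ParsedName) else parse_entry_name(a)
    pb = b if isinstance(b, ParsedName) else parse_entry_name(b)
    return pa.species == pb.species and _genus_match(pa.genus, pb.genus)


@dataclass
class TaxGroupRegistry:
    """Named sets of species whose 16S sequences are nearly identical."""

    groups: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: list[tuple[ParsedName, str]] = []
        norm: dict[str, set[str]] = {}
        for gname, members in self.groups.items():
            canon = set()
            for m in members:
                p = parse_entry_name(m)
                for q, other in seen:
                    if other != gname and species_match(p, q):
                        raise ValueError(
                            f"species {m!r} appears in both {other!r} and {gname!r}"
                        )
                seen.append((p, gname))
                canon.add(p.binomial)
            norm[gname] = canon
        self.groups = norm

    def group_of(self, species_name: str | ParsedName) -> str | None:
        p = species_name if isinstance(species_name, ParsedName) else parse_entry_name(species_name)
        for gname, members in self.groups.items():
            if any(species_match(p, m) for m in members):
                return gname
        return None

    def members(self, group: str) -> set[str]:
        return set(self.groups[group])

    @classmethod
    def from_yaml(cls, path) -> "TaxGroupRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        groups = {str(k): set(v) for k, v in doc.get("groups", doc).items()}
        return cls(groups=groups)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"groups": {k: sorted(v) for k, v in self.groups.items()}}, fh)


def default_registry() -> TaxGroupRegistry:
    """The two Bacillus taxonomic groups relevant to cleanroom archives."""
    return TaxGroupRegistry(groups={
        "pumilus_group": {
            "Bacillus pumilus", "Bacillus safensis",
            "Bacillus australimaris", "Bacillus zhangzhouensis",
        },
        "cereus_group": {
            "Bacillus cereus", "Bacillus thuringiensis", "Bacillus anthracis",
        },
    })


@dataclass
class ConcordanceRecord:
    isolate_id: str
    species_16s: str
    identity_16s: float
    maldi_entry: str
    maldi_score: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def categorize(
    isolate_id: str,
    species_16s: str,
    identity_16s: float,
    maldi_entry: str,
    maldi_score: float,
    *,
    registry: TaxGroupRegistry | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    typed_species: Iterable[str] | None = None,
    maldi_level: str | None = None,
) -> ConcordanceRecord:
    """Assign one isolate's pair of calls to a concordance category.

    ``typed_species`` — when given — lists the species with a type-strain
    MSP in the library; a discordant call inside a registered taxonomic
    group whose competing members lack type-strain spectra is reported as
    ``taxgroup_unresolved`` instead of confidently discordant.
    ``maldi_level`` may carry the consensus level ("species", "genus",
    "unidentified") from the replicate rubric; without it, the score alone
    is compared to the threshold.  Raising the threshold can only move
    records toward ``potentially_novel``.
    """
    unidentified = (maldi_level == "unidentified" if maldi_level is not None
                    else maldi_score < threshold)
    if maldi_level is None and maldi_score < threshold:
        unidentified = True

    def make(category: str) -> ConcordanceRecord:
        return ConcordanceRecord(isolate_id, species_16s, identity_16s,
                                 maldi_entry, maldi_score, category)

    if unidentified or maldi_score < threshold:
        return make("potentially_novel")

    p16 = parse_entry_name(species_16s)
    pms = parse_entry_name(maldi_entry)
    if not _genus_match(p16.genus, pms.genus):
        raise ConcordanceError(
            f"{isolate_id}: genus mismatch between methods "
            f"({p16.genus!r} vs {pms.genus!r})"
        )
    if species_match(p16, pms):
        return make("species_concordant")

    if registry is not None and typed_species is not None:
        gname = registry.group_of(p16)
        if gname is not None:
            typed = {parse_entry_name(t).binomial for t in typed_species}
            missing = [m for m in registry.members(gname)
                       if not any(species_match(m, t) for t in typed)]
            if missing:
                return make("taxgroup_unresolved")

    if maldi_level == "genus":
        return make("genus_only")
    if pms.is_type_strain or (
        typed_species is not None
        and any(species_match(pms, t) for t in typed_species)
    ):
        return make("maldi_confident_discordant")
    return make("genus_only")


def tabulate(records: Sequence[ConcordanceRecord]) -> dict:
    """Category counts plus the genus-level agreement count.

    Counts always partition the record set; every record that passed
    ``categorize`` agrees at the genus level.
    """
    counts = Counter(r.category for r in records)
    out = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    out["n_records"] = len(records)
    out["genus_agreement"] = len(records)
    return out
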