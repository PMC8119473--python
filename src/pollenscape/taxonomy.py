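"""Botanical name normalization.

Municipal tree inventories and allergenicity lookup tables spell the same
taxon in many ways ("ACER  platanoides", "Platanus X acerifolia",
"Tilia cordata 'Greenspire'").  This module parses raw name strings into a
canonical :class:`TaxonName` used as the join key throughout the pipeline.

Parsing rules:

* case-insensitive; diacritics are stripped to ASCII before matching;
* a standalone "x", "X" or "×" token between genus and epithet (or a
  "×" glued to the epithet) marks a hybrid and is removed from the key;
* cultivar names are recognized only when wrapped in single quotes;
* "sp.", "spp." and "species" force genus rank;
* infraspecific ranks (var., subsp., ssp., f.) are collapsed to species rank
  and flagged, since allergenicity sources do not resolve below species.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "TaxonName",
    "SynonymTable",
    "TaxonParseError",
    "normalize_name",
    "taxon_key",
]

_GENUS_RE = re.compile(r"^[A-Z][a-z-]+$")
_EPITHET_RE = re.compile(r"^[a-z-]+$")

# tokens that force genus rank (unidentified species)
_SP_TOKENS = {"sp", "sp.", "spp", "spp.", "species"}
# infraspecific rank markers: everything from here on is collapsed
_INFRA_TOKENS = {"var.", "var", "subsp.", "subsp", "ssp.", "ssp", "f.", "forma"}
_HYBRID_TOKENS = {"x", "×"}

_CULTIVAR_RE = re.compile(r"['‘’]([^'‘’]+)['‘’]")


class TaxonParseError(ValueError):
    """Raised for a name string with no leading alphabetic token.

    Carries the offending raw string so callers can log and decide whether
    to drop the record or abort.
    """

    def __init__(self, raw: str, reason: str = "no leading alphabetic token"):
        self.raw = raw
        super().__init__(f"unparseable taxon name {raw!r}: {reason}")


@dataclass(frozen=True)
class TaxonName:
    """A parsed botanical name.

    ``rank`` is "genus" when no epithet was resolved, "cultivar" when a
    quoted cultivar is present, "species" otherwise.  The hybrid flag is
    carried for display but never enters join keys: a hybrid and its
    marker-free spelling are the same taxon for lookup purposes.
    """

    raw: str = field(compare=False)
    genus: str = ""
    epithet: Optional[str] = None
    hybrid: bool = False
    cultivar: Optional[str] = None
    infraspecific_collapsed: bool = field(default=False, compare=False)

    @property
    def rank(self) -> str:
        if self.cultivar is not None:
            return "cultivar"
        return "species" if self.epithet else "genus"

    @property
    def canonical_text(self) -> str:
        """Round-trippable text form: parsing it again yields an equal name."""
        parts = [self.genus]
        if self.hybrid:
            parts.append("x")
        if self.epithet:
            parts.append(self.epithet)
        if self.cultivar:
            parts.append(f"'{self.cultivar}'")
        return " ".join(parts)

    def key(self, level: Optional[str] = None) -> str:
        return taxon_key(self, level or self.rank)


def _strip_diacritics(s: str) -> str:
    # NFKD leaves the multiplication sign (hybrid marker) intact, which is
    # what we want: it is handled as a token, not a diacritic.
    decomposed = unicodedata.normalize("NFKD", s)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def normalize_name(raw: str, synonyms: "Optional[SynonymTable]" = None) -> TaxonName:
    """Parse and normalize a raw botanical name string.

    Lexical normalization runs first; synonym substitution (if a table is
    given) is applied once afterwards, on the species key and then the genus
    key.  Raises :class:`TaxonParseError` when no genus token can be found.
    """
    if raw is None:
        raise TaxonParseError(str(raw), "empty")
    text = str(raw).strip()
    if not text:
        raise TaxonParseError(raw, "empty")

    cultivar = None
    m = _CULTIVAR_RE.search(text)
    if m:
        cultivar = " ".join(m.group(1).split()).strip()
        text = text[: m.start()] + " " + text[m.end():]
        if not cultivar:
            cultivar = None

    text = _strip_diacritics(text)
    tokens = text.replace("×", " × ").split()

    hybrid = False
    clean: list[str] = []
    for tok in tokens:
        if tok.lower() in _HYBRID_TOKENS:
            hybrid = True
            continue
        clean.append(tok)
    if not clean or not clean[0][0].isalpha():
        raise TaxonParseError(raw)

    genus = clean[0].lower().capitalize()
    if not _GENUS_RE.match(genus):
        # strip trailing punctuation such as "Acer,"
        genus = re.sub(r"[^a-z-]", "", clean[0].lower()).capitalize()
        if not _GENUS_RE.match(genus):
            raise TaxonParseError(raw, f"invalid genus token {clean[0]!r}")

    epithet: Optional[str] = None
    infraspecific = False
    if len(clean) > 1:
        tok = clean[1].lower()
        if tok in _SP_TOKENS:
            epithet = None
        else:
            cand = re.sub(r"[^a-z-]", "", tok)
            if cand and _EPITHET_RE.match(cand):
                epithet = cand
        # anything past the epithet: detect infraspecific markers, ignore
        # authority strings (unquoted capitalized tokens are NOT cultivars)
        for tok in clean[2:]:
            if tok.lower() in _INFRA_TOKENS:
                infraspecific = True
                break

    if cultivar is not None and epithet is None:
        # genus-level cultivar / trade name: keep it, rank stays cultivar
        pass

    name = TaxonName(
        raw=str(raw),
        genus=genus,
        epithet=epithet,
        hybrid=hybrid,
        cultivar=cultivar,
        infraspecific_collapsed=infraspecific,
    )
    if synonyms is not None:
        name = synonyms.apply(name)
    return name


def taxon_key(name: TaxonName, level: str) -> str:
    """Canonical join key for ``name`` at ``level``.

    genus key = "Genus"; species key = "Genus epithet" (hybrid marker
    excluded); cultivar key = species key + "|" + casefolded cultivar.
    """
    if level == "genus":
        return name.genus
    if level == "species":
        if not name.epithet:
            raise ValueError(
                f"species key unavailable for {name.genus!r}: rank is {name.rank}"
            )
        return f"{name.genus} {name.epithet}"
    if level == "cultivar":
        if not name.cultivar:
            raise ValueError(
                f"cultivar key unavailable for {name.canonical_text!r}: "
                f"rank is {name.rank}"
            )
        base = (
            f"{name.genus} {name.epithet}" if name.epithet else name.genus
        )
        return f"{base}|{name.cultivar.casefold()}"
    raise ValueError(f"unknown key level {level!r}")


@dataclass
class SynonymTable:
    """Mapping from a normalized name key to its accepted name key.

    The table is a single fixed-point step: an accepted name is never itself
    a key (enforced at load), so applying the table twice equals applying it
    once.  An empty table is valid and means "no synonymy".
    """

    mapping: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.mapping.items():
            if dst in self.mapping:
                raise ValueError(
                    f"synonym table is not a fixed point: accepted name "
                    f"{dst!r} (for {src!r}) is itself a synonym key"
                )
            if src == dst:
                raise ValueError(f"self-referential synonym entry {src!r}")

    def __len__(self) -> int:
        return len(self.mapping)

    def apply(self, name: TaxonName) -> TaxonName:
        """Substitute ``name`` by its accepted name, if listed.

        The species key is tried first, then the genus key; a genus-level
        synonym rewrites only the genus token.
        """
        if name.epithet:
            hit = self.mapping.get(f"{name.genus} {name.epithet}")
            if hit is not None:
                accepted = normalize_name(hit)
                return TaxonName(
                    raw=name.raw,
                    genus=accepted.genus,
                    epithet=accepted.epithet or name.epithet,
                    hybrid=name.hybrid or accepted.hybrid,
                    cultivar=name.cultivar,
                    infraspecific_collapsed=name.infraspecific_collapsed,
                )
        hit = self.mapping.get(name.genus)
        if hit is not None:
            accepted = normalize_name(hit)
            return TaxonName(
                raw=name.raw,
                genus=accepted.genus,
                epithet=name.epithet,
                hybrid=name.hybrid,
                cultivar=name.cultivar,
                infraspecific_collapsed=name.infraspecific_collapsed,
            )
        return name

    @classmethod
    def from_file(cls, path) -> "SynonymTable":
        """Load a 2-column delimited file with header ``source,accepted``."""
        mapping: dict[str, str] = {}
        prov: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {
                "source",
                "accepted",
            }.issubset({f.strip().lower() for f in reader.fieldnames}):
                raise ValueError(
                    f"synonym table {path} must have header 'source,accepted'"
                )
            for row in reader:
                row = {k.strip().lower(): v for k, v in row.items() if k}
                src_name = normalize_name(row["source"])
                src = src_name.key("species" if src_name.epithet else "genus")
                mapping[src] = row["accepted"].strip()
                prov[src] = row.get("notes", "") or ""
        # store accepted values as normalized keys so the fixed-point check
        # compares like with like
        norm_map: dict[str, str] = {}
        for src, dst in mapping.items():
            dst_name = normalize_name(dst)
            norm_map[src] = dst_name.key(
                "species" if dst_name.epithet else "genus"
            )
        return cls(mapping=norm_map, provenance=prov)
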