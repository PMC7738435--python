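"""Guild assignment: syntrophs, methanogens, fermenters, WAS-associated.

Known syntrophs and known methanogens are recognized by their taxonomic
affiliation (case-insensitive substring match of curated lineage keywords
against the full lineage string, so both family- and genus-level keywords
work). Every remaining OTU with an estimated growth rate is classified by
the sign of that rate: non-negative rates mark fermenters growing in the
reactor; negative rates mark feed-borne (waste-activated-sludge-associated)
biomass that is being decomposed rather than growing. OTUs whose rate is
undefined (washed out, or absent everywhere) and that match no taxonomy
keyword are left unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .egmb_core import GrowthRateRecord, GrowthStatus

__all__ = [
    "Guild",
    "GuildRuleSet",
    "GuildAssignment",
    "classify_otu",
    "classify_table",
    "default_rules",
    "load_rules",
    "write_guild_table",
]

GUILDS = ("syntroph", "methanogen", "fermenter", "was_associated", "unclassified")
Guild = str  # one of GUILDS


@dataclass(frozen=True)
class GuildRuleSet:
    """Curated lineage keywords for the two taxonomy-recognized guilds."""

    syntroph_taxa: tuple[str, ...]
    methanogen_taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.syntroph_taxa or not self.methanogen_taxa:
            raise ValueError("keyword lists must be non-empty")
        overlap = {t.lower() for t in self.syntroph_taxa} & {
            t.lower() for t in self.methanogen_taxa
        }
        if overlap:
            raise ValueError(f"syntroph/methanogen keyword lists overlap: {sorted(overlap)}")

    @staticmethod
    def empty_allowed(syntrophs: Sequence[str], methanogens: Sequence[str]) -> "GuildRuleSet":
        """Construct without the non-empty check (for sign-rule-only classification)."""
        rs = object.__new__(GuildRuleSet)
        object.__setattr__(rs, "syntroph_taxa", tuple(syntrophs))
        object.__setattr__(rs, "methanogen_taxa", tuple(methanogens))
        return rs


@dataclass(frozen=True)
class GuildAssignment:
    otu_id: str
    guild: Guild
    rule_fired: str


def _match(taxonomy: str, keywords: Sequence[str]) -> str | None:
    hay = taxonomy.lower()
    for kw in keywords:
        if kw.lower() in hay:
            return kw
    return None


def classify_otu(
    taxonomy: str, record: GrowthRateRecord, rules: GuildRuleSet
) -> GuildAssignment:
    """Assign one OTU to a guild.

    Precedence: syntroph keyword match > methanogen keyword match > growth-
    rate sign rule. An exact zero rate is binned as fermenter (a maintained
    population; the dichotomy is negative vs non-negative). Archaea that
    match no methanogen keyword fall through to the sign rule with a
    warning, since no rule exists for non-methanogen archaea.
    """
    kw = _match(taxonomy, rules.syntroph_taxa)
    if kw is not None:
        return GuildAssignment(record.otu_id, "syntroph", f"taxonomy:{kw}")
    kw = _match(taxonomy, rules.methanogen_taxa)
    if kw is not None:
        return GuildAssignment(record.otu_id, "methanogen", f"taxonomy:{kw}")
    if record.status is not GrowthStatus.ESTIMATED or record.mu_per_d is None:
        return GuildAssignment(record.otu_id, "unclassified", f"status:{record.status.value}")
    if "archaea" in taxonomy.lower():
        warnings.warn(
            f"OTU {record.otu_id!r} is archaeal but matches no methanogen keyword; "
            "falling through to the growth-rate sign rule",
            stacklevel=2,
        )
    if record.mu_per_d < 0:
        return GuildAssignment(record.otu_id, "was_associated", "sign:mu<0")
    return GuildAssignment(record.otu_id, "fermenter", "sign:mu>=0")


def classify_table(
    records: Iterable[GrowthRateRecord],
    rules: GuildRuleSet | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> list[GuildAssignment]:
    """Classify every record; taxonomy defaults to each record's own lineage."""
    if rules is None:
        rules = default_rules()
    out = []
    for r in records:
        tax = taxonomy[r.otu_id] if taxonomy is not None else r.taxonomy
        out.append(classify_otu(tax, r, rules))
    return out


def load_rules(path: str | Path) -> GuildRuleSet:
    """Read a rule file: one keyword per line under [syntrophs] / [methanogens]
    section headers; '#' starts a comment."""
    sections: dict[str, list[str]] = {"syntrophs": [], "methanogens": []}
    current: list[str] | None = None
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in sections:
                raise ValueError(f"{path}: unknown section [{name}]")
            current = sections[name]
            continue
        if current is None:
            raise ValueError(f"{path}: keyword {line!r} before any section header")
        current.append(line)
    return GuildRuleSet(tuple(sections["syntrophs"]), tuple(sections["methanogens"]))


def default_rules() -> GuildRuleSet:
    """The packaged rule set (editable data file shipped with the package)."""
    return load_rules(Path(__file__).parent / "data" / "guild_rules.txt")


def write_guild_table(
    records: Sequence[GrowthRateRecord],
    assignments: Sequence[GuildAssignment],
    path: str | Path,
) -> None:
    """Growth-rate TSV with guild and rule columns appended."""
    from .egmb_core import _fmt_mu

    by_id = {a.otu_id: a for a in assignments}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "otu_id\ttaxonomy\tp_reactor\tp_feed\tmu_per_day\tstatus\t"
            "steady_state_flag\tguild\trule_fired\n"
        )
        for r in records:
            a = by_id[r.otu_id]
            flag = "NA" if r.steady_state_flag is None else str(r.steady_state_flag).lower()
            fh.write(
                f"{r.otu_id}\t{r.taxonomy}\t{r.p_reactor:.6g}\t{r.p_feed:.6g}\t"
                f"{_fmt_mu(r.mu_per_d)}\t{r.status.value}\t{flag}\t{a.guild}\t{a.rule_fired}\n"
            )
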