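"""In-silico protease digestion for negative-set construction.

Candidate non-bioactive peptides are produced by cleaving source proteins with
empirical protease specificity rules (trypsin, chymotrypsin at high or low
specificity), in the style of PeptideCutter/Keil rule tables. A rule names the
P1 residues after which the backbone is cut, per-P1 sets of P1' residues that
veto the cut, and optional longer-context exception patterns. Rules ship as an
auditable JSON data file and can be extended or replaced.

Coordinates are 0-based: site ``i`` means the bond AFTER residue ``i`` is cut,
so a protein of length ``n`` with sites ``s1 < s2 < ...`` yields fragments
``seq[0:s1+1], seq[s1+1:s2+1], ..., seq[sk+1:n]``. Concatenating the fragments
in order reconstructs the protein exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from simpep.peptide_io import Peptide, PeptideSet

_RULES_RESOURCE = "cleavage_rules.json"


class DigestionError(Exception):
    """Digestion configuration or input problem."""


@dataclass(frozen=True)
class ExceptionPattern:
    """Longer-context override of the basic P1/P1' rule.

    ``pattern`` is matched as a substring; ``cut_index`` is the 0-based offset
    within the pattern of the residue whose following bond is affected;
    ``action`` is ``"veto"`` (suppress a cut the basic rule would make) or
    ``"allow"`` (re-enable a cut the P1' block would veto).
    """

    pattern: str
    cut_index: int
    action: str

    def __post_init__(self) -> None:
        if self.action not in ("veto", "allow"):
            raise DigestionError(f"unknown exception action {self.action!r}")
        if not (0 <= self.cut_index < len(self.pattern)):
            raise DigestionError(f"cut_index {self.cut_index} outside pattern {self.pattern!r}")


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cleave after ``cleave_after`` unless vetoed."""

    name: str
    cleave_after: frozenset
    blocked_by_next: dict = field(default_factory=dict)
    exceptions: tuple = ()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise DigestionError(f"rule {self.name!r}: cleave_after is empty")
        extra = set(self.blocked_by_next) - set(self.cleave_after)
        if extra:
            raise DigestionError(
                f"rule {self.name!r}: blocked_by_next keys {sorted(extra)} not in cleave_after"
            )


def _builtin_rule_data() -> dict:
    text = resources.files("simpep.data").joinpath(_RULES_RESOURCE).read_text(encoding="utf-8")
    return json.loads(text)


def load_rules(path: Optional[Path] = None) -> dict[str, CleavageRule]:
    """Load named cleavage rules from JSON (the packaged table by default)."""
    data = json.loads(Path(path).read_text(encoding="utf-8")) if path else _builtin_rule_data()
    rules = {}
    for name, spec in data.items():
        if name.startswith("_"):
            continue
        rules[name] = CleavageRule(
            name=name,
            cleave_after=frozenset(spec["cleave_after"]),
            blocked_by_next={k: frozenset(v) for k, v in spec.get("blocked_by_next", {}).items()},
            exceptions=tuple(
                ExceptionPattern(e["pattern"], e["cut_index"], e["action"])
                for e in spec.get("exceptions", ())
            ),
        )
    return rules


def get_rule(name: str) -> CleavageRule:
    rules = load_rules()
    try:
        return rules[name]
    except KeyError:
        raise DigestionError(f"unknown cleavage rule {name!r}; available: {sorted(rules)}") from None


@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one protein with one rule.

    Invariant: ``"".join(f.sequence for f in peptides.members) == protein
    sequence`` and ``sites`` strictly increasing with no site at the final
    residue (which would create an empty fragment).
    """

    protein_id: str
    enzyme: str
    sites: tuple
    peptides: PeptideSet


def _exception_votes(sequence: str, rule: CleavageRule, i: int) -> Optional[str]:
    """Return 'veto'/'allow' if an exception pattern covers the bond after i."""
    decision = None
    for exc in rule.exceptions:
        k = len(exc.pattern)
        start = i - exc.cut_index
        if start >= 0 and sequence[start:start + k] == exc.pattern:
            # veto wins over allow if both somehow match
            if exc.action == "veto":
                return "veto"
            decision = "allow"
    return decision


def cleavage_sites(protein: Peptide, rule: CleavageRule) -> tuple:
    """Predict cut positions (0-based, bond after the indexed residue).

    Position ``i`` is a site iff the residue is in ``cleave_after``, it is not
    the final residue, the following residue does not veto it, and no
    exception pattern vetoes it (an ``allow`` pattern can override the
    P1'-block).
    """
    seq = protein.sequence
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] not in rule.cleave_after:
            continue
        vote = _exception_votes(seq, rule, i)
        if vote == "veto":
            continue
        blocked = seq[i + 1] in rule.blocked_by_next.get(seq[i], frozenset())
        if blocked and vote != "allow":
            continue
        sites.append(i)
    return tuple(sites)


def digest(protein: Peptide, rule: CleavageRule) -> DigestResult:
    """Cleave a protein into the maximal fragments between consecutive sites."""
    seq = protein.sequence
    sites = cleavage_sites(protein, rule)
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    members = []
    for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        members.append(
            Peptide(
                id=f"{protein.id}|{rule.name}|{lo}-{hi}",
                sequence=seq[lo:hi],
                source=f"{protein.id} {rule.name} fragment {k}",
            )
        )
    fragments = PeptideSet(f"{protein.id}:{rule.name}", members)
    assert "".join(fragments.sequences) == seq
    return DigestResult(protein.id, rule.name, sites, fragments)


def build_negative_set(
    proteins: PeptideSet,
    rules: Sequence[CleavageRule],
    min_length: int = 1,
    max_length: Optional[int] = None,
    dedup: bool = False,
    label: Optional[str] = None,
    name: str = "negatives",
) -> PeptideSet:
    """Union of digests of every protein under every rule, filtered last.

    Each fragment is tagged with its source protein and enzyme. Output order
    is deterministic: by protein (input order), then rule (given order), then
    position. ``dedup`` drops later fragments whose sequence was already
    emitted. Length filters are applied after the union.
    """
    if len(proteins) == 0 or not rules:
        raise DigestionError("need at least one protein and one rule")
    members: list[Peptide] = []
    seen: set[str] = set()
    for protein in proteins:
        for rule in rules:
            for frag in digest(protein, rule).peptides:
                if len(frag) < min_length:
                    continue
                if max_length is not None and len(frag) > max_length:
                    continue
                if dedup:
                    if frag.sequence in seen:
                        continue
                    seen.add(frag.sequence)
                if label is not None:
                    frag = Peptide(frag.id, frag.sequence, label=label, source=frag.source)
                members.append(frag)
    if not members:
        import logging

        logging.getLogger(__name__).warning(
            "negative set %r is empty after filtering", name
        )
    return PeptideSet(name, members)
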