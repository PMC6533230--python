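"""Rule-based extraction of mixture descriptions from plain text.

Vendor-catalog lines like ``"Trimethyl(trifluoromethyl)silane solution
2 M in THF"`` are converted into Mixfile trees by a recursive procedure:
the full text becomes the root component's name, then at every node

1. an ordered list of regex rules is applied to fixpoint — *remove* rules
   delete superfluous words, *replace* rules rewrite text, *concentration*
   rules move a quantity span (``≥ 97.0%``, ``2 M``, ``40 g/L`` …) out of
   the name into the quantity fields, and *branch* rules split the name
   at a separator (``{solute} in {solvent}``) into child components, each
   processed recursively;
2. the remaining name is checked against a lookup table, whose entries
   either attach a known structure (``THF`` → tetrahydrofuran) or replace
   the component with a whole sub-mixture (``hexanes``, ``xylenes``);
3. unresolved names may be handed to a pluggable name-to-structure
   resolver (the contract an external program such as OPSIN would fill);
   resolver failures are swallowed and the node stays name-only.

In the null case where nothing applies, the result is a single node whose
name is the unmodified input text. Every rule firing is recorded in an
optional log so extractions can be audited.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from .compounds import structure_payload
from .errors import RuleCycleError
from .model import MixComponent, Mixfile, Quantity, normalize_relation

logger = logging.getLogger(__name__)

RULE_KINDS = ("remove", "replace", "concentration", "branch")

#: Bounded number of rule passes per node before declaring a cycle.
MAX_PASSES = 32


@dataclass
class ExtractionRule:
    """One rewrite rule.

    ``kind`` semantics:

    - ``remove``: delete the matched span from the name.
    - ``replace``: substitute the matched span with ``replacement``.
    - ``concentration``: parse the matched span as a quantity, assign it
      to the component and delete the span from the name; skipped if the
      component already has a quantity.
    - ``branch``: the pattern is a *separator*; the name is split at the
      first match lying outside parentheses, and each part becomes a
      child component (processed recursively).

    Rules are applied in ascending ``priority`` order, restarting from the
    top after every change, until no rule matches.
    """

    kind: str
    pattern: str
    replacement: str = ""
    priority: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        self.regex = re.compile(self.pattern, re.IGNORECASE)


@dataclass(frozen=True)
class RuleFiring:
    """Audit record of one rule application."""

    rule: str
    kind: str
    before: str
    after: Optional[str]
    captured: str


@dataclass
class LookupEntry:
    """Name → structure-or-subtree table entry.

    Exactly one of ``structure`` (a payload dict with name/smiles/inchi/
    inchiKey, copied onto the component) or ``subtree`` (a whole
    :class:`MixComponent` that replaces the component, which keeps its
    quantity) must be set. Matching is case-insensitive with whitespace
    collapsed.
    """

    names: tuple[str, ...]
    structure: Optional[dict] = None
    subtree: Optional[MixComponent] = None

    def __post_init__(self) -> None:
        if (self.structure is None) == (self.subtree is None):
            raise ValueError("entry must have exactly one of structure or subtree")


class NameResolver(Protocol):
    """Contract for an external name-to-structure converter: a pure
    lookup returning a structure payload dict or None."""

    def resolve(self, name: str) -> Optional[dict]: ...


# ---------------------------------------------------------------------------
# concentration-span recognition

_REL = r"(?P<rel>≥|≤|≈|>=|<=|~|>|<)"
# longest spellings first so e.g. "mmol/L" is not read as "mol/L"
_UNITS = (
    "mol/mol%|w/v%|w/w%|v/v%|mmol/L|μmol/L|umol/L|nmol/L|pmol/L|mol/L|"
    "mol/kg|mg/L|μg/L|ug/L|g/L|mM|μM|uM|nM|pM|M|%"
)
_NUM = r"\d+(?:\.\d+)?"
CONCENTRATION_PATTERN = (
    rf"(?<![\w.\-]){_REL}?\s*(?P<lo>{_NUM})"
    rf"(?:\s*[–—:]\s*(?P<hi>{_NUM}))?\s*"
    rf"(?P<units>{_UNITS})(?![\w/%])"
)
_CONC_RE = re.compile(CONCENTRATION_PATTERN)

#: shorthand unit spellings → Table-of-units common names
_UNIT_SYNONYMS = {
    "M": "mol/L",
    "mM": "mmol/L",
    "μM": "μmol/L",
    "uM": "μmol/L",
    "nM": "nmol/L",
    "pM": "pmol/L",
    "umol/L": "μmol/L",
    "ug/L": "μg/L",
}


def _number(text: str):
    return float(text) if "." in text else int(text)


def parse_concentration_text(span: str) -> Optional[Quantity]:
    """Parse a quantity span such as ``≥ 97.0%``, ``2 M`` or
    ``1.9–2.1 mol/L``; returns None when the text contains no
    recognizable quantity."""
    m = _CONC_RE.search(span)
    if not m:
        return None
    lo = _number(m.group("lo"))
    value = [lo, _number(m.group("hi"))] if m.group("hi") else lo
    units = m.group("units")
    units = _UNIT_SYNONYMS.get(units, units)
    relation = normalize_relation(m.group("rel")) if m.group("rel") else None
    return Quantity(value=value, relation=relation, units=units)


# ---------------------------------------------------------------------------
# rule application


def _paren_depth_ok(text: str, start: int) -> bool:
    depth = 0
    for ch in text[:start]:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
    return depth == 0


def _branch_split(name: str, rule: ExtractionRule) -> Optional[tuple[list[str], str]]:
    """Split at the first separator match outside parentheses; both sides
    must be non-empty. Returns (parts, separator text)."""
    for m in rule.regex.finditer(name):
        if not _paren_depth_ok(name, m.start()):
            continue
        left, right = name[:m.start()].strip(), name[m.end():].strip()
        if left and right:
            return [left, right], m.group(0)
    return None


def _apply_once(node: MixComponent, rule: ExtractionRule, log: Optional[list]) -> bool:
    """Try a single rule on a node; returns True if the node changed."""
    name = node.name
    if not name:
        return False
    if rule.kind == "branch":
        if node.contents:
            return False
        split = _branch_split(name, rule)
        if split is None:
            return False
        parts, separator = split
        node.contents = [MixComponent(name=p) for p in parts]
        node.name = None
        if log is not None:
            # `captured` records only the consumed separator; the parts
            # live on as the children's names
            log.append(RuleFiring(rule.name, "branch", name, None, separator))
        return True
    if rule.kind == "concentration":
        if node.quantity is not None and not node.quantity.is_empty:
            return False
        m = rule.regex.search(name)
        if not m:
            return False
        q = parse_concentration_text(m.group(0))
        if q is None:
            return False
        node.quantity = q
        node.name = (name[:m.start()] + " " + name[m.end():]).strip()
        if log is not None:
            log.append(RuleFiring(rule.name, "concentration", name, node.name, m.group(0)))
        return True
    # remove / replace
    replacement = "" if rule.kind == "remove" else rule.replacement
    new_name, n = rule.regex.subn(replacement, name)
    new_name = new_name if rule.kind == "replace" else new_name.strip()
    if n == 0 or new_name == name:
        return False
    if log is not None:
        log.append(RuleFiring(rule.name, rule.kind, name, new_name, ""))
    node.name = new_name
    return True


def apply_rules(
    node: MixComponent,
    rules: Sequence[ExtractionRule],
    log: Optional[list] = None,
    max_passes: int = MAX_PASSES,
) -> MixComponent:
    """Apply rules to a node (in priority order, to fixpoint) and
    recursively to any children created by branch rules. The node is
    mutated in place and returned.

    Raises :class:`RuleCycleError` if rules keep rewriting the name after
    ``max_passes`` changes (e.g. two replace rules that undo each other).
    """
    ordered = sorted(rules, key=lambda r: r.priority)
    n_before = len(node.contents)
    for _ in range(max_passes):
        if not any(_apply_once(node, rule, log) for rule in ordered):
            break
    else:
        raise RuleCycleError(f"rules did not reach a fixpoint on {node.name!r}")
    for child in node.contents[n_before:]:
        apply_rules(child, rules, log, max_passes)
    return node


# ---------------------------------------------------------------------------
# lookup table

def _norm_name(name: str) -> str:
    return " ".join(name.casefold().split())


def lookup_name(name: str, table: Sequence[LookupEntry]) -> Optional[LookupEntry]:
    """Find the table entry matching a name (case-insensitive, whitespace
    collapsed)."""
    key = _norm_name(name)
    for entry in table:
        if any(_norm_name(n) == key for n in entry.names):
            return entry
    return None


def _apply_structure(node: MixComponent, payload: dict) -> None:
    node.name = payload.get("name", node.name)
    for f in ("molfile", "formula", "inchi", "inchiKey", "smiles"):
        if payload.get(f) is not None:
            setattr(node, f, payload[f])


def _apply_entry(node: MixComponent, entry: LookupEntry) -> None:
    if entry.structure is not None:
        _apply_structure(node, entry.structure)
        return
    # subtree entries overwrite the component completely, keeping its quantity
    sub = copy.deepcopy(entry.subtree)
    keep_quantity = node.quantity
    for f in ("name", "description", "synonyms", "molfile", "formula", "inchi",
              "inchiKey", "smiles", "quantity", "identifiers", "links",
              "contents", "extras"):
        setattr(node, f, getattr(sub, f))
    if keep_quantity is not None:
        node.quantity = keep_quantity


def _isomer_subtree(name: str, isomers: list[str]) -> MixComponent:
    return MixComponent(
        name=name,
        contents=[MixComponent(**structure_payload(i)) for i in isomers],
    )


def default_lookup_table() -> list[LookupEntry]:
    """Starter lookup table: common solvents and the classic
    mixture-valued names.

    "hexanes" is enumerated as n-hexane, 2-methylpentane, 3-methylpentane
    and methylcyclopentane — the major C6 isomers of the commercial
    solvent; exact vendor compositions vary.
    """
    simple = [
        (("THF", "tetrahydrofuran"), "tetrahydrofuran"),
        (("DCM", "methylene chloride", "dichloromethane"), "dichloromethane"),
        (("toluene",), "toluene"),
        (("water", "H2O"), "water"),
        (("methanol", "MeOH"), "methanol"),
        (("ethanol", "EtOH"), "ethanol"),
        (("acetone",), "acetone"),
        (("chloroform",), "chloroform"),
        (("ether", "diethyl ether", "Et2O"), "diethyl ether"),
        (("acetonitrile", "MeCN", "ACN"), "acetonitrile"),
        (("pentane",), "pentane"),
        (("heptane",), "heptane"),
        (("benzene",), "benzene"),
    ]
    table = [LookupEntry(names, structure=structure_payload(canon)) for names, canon in simple]
    table.append(LookupEntry(
        ("hexanes", "hexane (mixture of isomers)"),
        subtree=_isomer_subtree(
            "hexanes",
            ["n-hexane", "2-methylpentane", "3-methylpentane", "methylcyclopentane"],
        ),
    ))
    table.append(LookupEntry(
        ("xylenes", "xylene (mixture of isomers)"),
        subtree=_isomer_subtree("xylenes", ["o-xylene", "m-xylene", "p-xylene"]),
    ))
    return table


def default_rules() -> list[ExtractionRule]:
    """Starter rule set covering the common vendor-catalog shapes:
    purity suffixes, "x M in y" solute/solvent pairs, the superfluous
    word "solution", and whitespace/punctuation tidying."""
    return [
        ExtractionRule("branch", r"\s+in\s+", priority=10, name="solute-in-solvent"),
        ExtractionRule("concentration", CONCENTRATION_PATTERN, priority=20, name="quantity-span"),
        ExtractionRule("remove", r"\bsolutions?\b", priority=30, name="superfluous-solution"),
        ExtractionRule("replace", r"\s{2,}", " ", priority=40, name="collapse-whitespace"),
        ExtractionRule("remove", r"^[\s,;]+|[\s,;]+$", priority=50, name="trim"),
    ]


# ---------------------------------------------------------------------------
# the full pipeline


def extract_mixture(
    text: str,
    rules: Optional[Sequence[ExtractionRule]] = None,
    table: Optional[Sequence[LookupEntry]] = None,
    resolver: Optional[NameResolver] = None,
    log: Optional[list] = None,
) -> Mixfile:
    """Convert one plain-text mixture description into a Mixfile.

    Per node the order is rules → lookup table → resolver. With empty
    rules and an empty table the output is always a single node named
    with the input text.
    """
    if not text or not text.strip():
        raise ValueError("empty mixture description")
    if rules is None:
        rules = default_rules()
    if table is None:
        table = default_lookup_table()
    root = MixComponent(name=text.strip())
    apply_rules(root, rules, log)
    for node, _depth, _path in list(root.walk()):
        if not node.name or node.has_structure:
            continue
        entry = lookup_name(node.name, table)
        if entry is not None:
            _apply_entry(node, entry)
            continue
        if resolver is not None:
            try:
                payload = resolver.resolve(node.name)
            except Exception:
                logger.warning("name resolver failed on %r", node.name, exc_info=True)
                continue
            if payload:
                _apply_structure(node, payload)
    return Mixfile(root=root)
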