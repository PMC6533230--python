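"""String-level mixture analytics on MInChI notation.

Because a MInChI component layer is a sorted list of InChI fragments,
structure containment, shared-ingredient detection and even concentration
equivalence (via the molecular formula embedded in each fragment) can all
be decided with plain string manipulation — no chemistry engine needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import MInChIFormatError
from .minchi import MInChIString, split_minchi
from .units import formula_from_inchi, molecular_weight, parse_formula, strip_inchi_prefix

#: Default relative tolerance for concentration equivalence. 90 g/L of
#: dimethylamine is 1.996 mol/L, sold as "2 M nominal"; 5% covers such
#: nominal-vs-computed gaps.
DEFAULT_REL_TOL = 0.05

_TOKEN_RE = re.compile(
    r"^(?P<rel>>=|<=|~|<|>)?"
    r"(?P<a>\d+(?:\.\d+)?(?:e[+-]?\d+)?)"
    r"(?::(?P<b>\d+(?:\.\d+)?(?:e[+-]?\d+)?))?"
    r"(?P<code>[a-z]{2})$"
)


@dataclass(frozen=True)
class ConcToken:
    """A parsed concentration token: an interval (points are degenerate
    intervals) plus the two-letter MInChI unit code. Relation prefixes are
    parsed but not used in comparisons."""

    low: float
    high: float
    code: str
    relation: Optional[str] = None


def parse_token(token: str) -> Optional[ConcToken]:
    """Parse one concentration-layer token; empty tokens (unspecified
    concentration) return None."""
    if token == "":
        return None
    m = _TOKEN_RE.match(token)
    if not m:
        raise MInChIFormatError(f"malformed concentration token {token!r}")
    low = float(m.group("a"))
    high = float(m.group("b")) if m.group("b") else low
    return ConcToken(low, high, m.group("code"), m.group("rel"))


def _as_minchi(m: Union[str, MInChIString]) -> MInChIString:
    return m if isinstance(m, MInChIString) else split_minchi(m)


def contains_structure(minchi: Union[str, MInChIString], query: str, *, substring: bool = False) -> bool:
    """Is the query structure one of the mixture's components?

    The query may be a full ``InChI=1S/...`` identifier or a bare
    fragment. By default the match is delimiter-bounded — the fragment
    must equal one ``&``-delimited component entry — which avoids the
    false positives of a raw substring scan. Pass ``substring=True`` for
    the simpler indexOf-style semantics.
    """
    fragment = strip_inchi_prefix(query)
    parts = _as_minchi(minchi)
    if substring:
        return fragment in "&".join(parts.components)
    return fragment in parts.components


def shared_components(a: Union[str, MInChIString], b: Union[str, MInChIString]) -> list[str]:
    """Sorted intersection of two mixtures' component fragments."""
    return sorted(set(_as_minchi(a).components) & set(_as_minchi(b).components))


# ---------------------------------------------------------------------------
# concentration equivalence


def _to_molar(tok: ConcToken, formula: Optional[str]) -> Optional[tuple[float, float]]:
    """Convert a token's interval to mol/L if possible: mr is already
    molar; wv (weight/volume fraction, g/mL) divides by MW."""
    if tok.code == "mr":
        return tok.low, tok.high
    if tok.code == "wv" and formula:
        mw = molecular_weight(parse_formula(formula))
        return tok.low * 1000.0 / mw, tok.high * 1000.0 / mw
    return None


def concentration_compatible(
    token_a: str,
    token_b: str,
    formula: Optional[str] = None,
    rel_tol: float = DEFAULT_REL_TOL,
) -> bool:
    """Do two concentration tokens describe the same concentration?

    Tokens with the same unit code are compared directly; a wv/mr pair is
    bridged through the molecular weight of ``formula``. Intervals are
    compared by overlap, points by relative difference ≤ ``rel_tol``;
    unit-code pairs with no defined conversion are incompatible. The
    check is symmetric in its two tokens.
    """
    ta, tb = parse_token(token_a), parse_token(token_b)
    if ta is None or tb is None:
        return ta is tb  # two unspecified concentrations agree trivially
    if ta.code == tb.code:
        ia, ib = (ta.low, ta.high), (tb.low, tb.high)
    else:
        ia = _to_molar(ta, formula)
        ib = _to_molar(tb, formula)
        if ia is None or ib is None:
            return False
    eps = rel_tol * max(abs(ia[1]), abs(ib[1]))
    return ia[1] >= ib[0] - eps and ib[1] >= ia[0] - eps


# ---------------------------------------------------------------------------
# layer-pair walking (mapping component indices to concentration tokens)


def _parse_layer_pair(indexing: str, concentration: str) -> list[tuple[Optional[int], str]]:
    """Walk the two layers (identical brace skeletons) in lockstep and
    return one ``(component index or None, concentration token)`` pair per
    tree node."""

    def parse(layer: str) -> list:
        # each node -> (children list, tail text); returns sibling list
        pos = 0

        def node():
            nonlocal pos
            children = []
            if pos < len(layer) and layer[pos] == "{":
                pos += 1
                children.append(node())
                while pos < len(layer) and layer[pos] == "&":
                    pos += 1
                    children.append(node())
                if pos >= len(layer) or layer[pos] != "}":
                    raise MInChIFormatError(f"unbalanced braces in layer {layer!r}")
                pos += 1
            start = pos
            while pos < len(layer) and layer[pos] not in "&{}":
                pos += 1
            return children, layer[start:pos]

        siblings = [node()]
        while pos < len(layer) and layer[pos] == "&":
            pos += 1
            siblings.append(node())
        if pos != len(layer):
            raise MInChIFormatError(f"trailing content in layer {layer!r}")
        return siblings

    pairs: list[tuple[Optional[int], str]] = []

    def zip_nodes(ni, nc):
        if len(ni[0]) != len(nc[0]):
            raise MInChIFormatError("indexing and concentration skeletons differ")
        for ci, cc in zip(ni[0], nc[0]):
            zip_nodes(ci, cc)
        idx_text = ni[1]
        if idx_text and not idx_text.isdigit():
            raise MInChIFormatError(f"non-numeric index token {idx_text!r}")
        pairs.append((int(idx_text) if idx_text else None, nc[1]))

    for si, sc in zip(parse(indexing), parse(concentration)):
        zip_nodes(si, sc)
    return pairs


def index_tokens(m: Union[str, MInChIString]) -> dict[int, list[str]]:
    """Map each component index (1-based) to the concentration tokens of
    every tree position where that component appears."""
    parts = _as_minchi(m)
    out: dict[int, list[str]] = {}
    for idx, token in _parse_layer_pair(parts.indexing, parts.concentration):
        if idx is not None:
            if not 1 <= idx <= len(parts.components):
                raise MInChIFormatError(f"index {idx} out of range")
            out.setdefault(idx, []).append(token)
    return out


@dataclass(frozen=True)
class SharedComponent:
    """One ingredient common to both mixtures, with the concentration
    tokens found at each of its tree positions and the equivalence
    verdict: ``compatible``, ``incompatible`` or ``unspecified`` (no
    concentration given on at least one side)."""

    fragment: str
    tokens_a: tuple[str, ...]
    tokens_b: tuple[str, ...]
    verdict: str


@dataclass
class MixtureComparison:
    shared: list[SharedComponent] = field(default_factory=list)
    only_a: list[str] = field(default_factory=list)
    only_b: list[str] = field(default_factory=list)

    @property
    def shared_count(self) -> int:
        return len(self.shared)


def compare_mixtures(
    a: Union[str, MInChIString],
    b: Union[str, MInChIString],
    rel_tol: float = DEFAULT_REL_TOL,
) -> MixtureComparison:
    """Full composition-and-concentration comparison of two MInChI
    strings.

    Shared components are matched to their concentration tokens through
    the indexing layer (all tree positions are considered when a fragment
    occurs more than once); the per-component verdict is ``compatible`` if
    any token pair agrees, ``incompatible`` if real tokens exist on both
    sides but none agree, and ``unspecified`` otherwise.
    """
    pa, pb = _as_minchi(a), _as_minchi(b)
    set_a, set_b = set(pa.components), set(pb.components)
    toks_a, toks_b = index_tokens(pa), index_tokens(pb)
    report = MixtureComparison(
        only_a=sorted(set_a - set_b),
        only_b=sorted(set_b - set_a),
    )
    for fragment in sorted(set_a & set_b):
        ta = tuple(toks_a.get(pa.components.index(fragment) + 1, []))
        tb = tuple(toks_b.get(pb.components.index(fragment) + 1, []))
        real_a = [t for t in ta if t]
        real_b = [t for t in tb if t]
        if not real_a or not real_b:
            verdict = "unspecified"
        else:
            formula = formula_from_inchi(fragment)
            if any(
                concentration_compatible(x, y, formula, rel_tol)
                for x in real_a
                for y in real_b
            ):
                verdict = "compatible"
            else:
                verdict = "incompatible"
        report.shared.append(SharedComponent(fragment, ta, tb, verdict))
    return report
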