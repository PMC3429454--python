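"""Shorthand lipid nomenclature: parsing, class assignment, standards, blocks.

Plasma lipidomics platforms report species at the *sum composition* level —
``PC(38:4)`` means a phosphatidylcholine whose acyl chains together carry 38
carbons and 4 double bonds — or, when MS/MS resolved the chains, at the chain
level, e.g. ``SM(d18:0/24:0)`` (sphingoid base d18:0 plus a 24:0 N-acyl).
An ``e`` suffix marks an ether-linked (alkyl) chain.  Peaks that could not be
distinguished between two species are reported joined by ``+`` or ``/``,
e.g. ``PC(37:4)/PE(40:4)``; the first-listed term is taken as the primary
identity and the alternatives are retained.

Eleven lipid classes are recognised: ceramides (Cer), lysophosphatidyl-
cholines (lysoPC) and -ethanolamines (lysoPE), phosphatidic acids (PA),
phosphatidylcholines (PC), phosphatidylethanolamines (PE), phosphatidyl-
glycerols (PG), phosphatidylinositols (PI), phosphatidylserines (PS),
sphingomyelins (SM) and triglycerides (TG).  Each class maps to the spiked
internal standard used to convert its peak intensities to concentrations,
and to one of eleven blocks for the multi-block regression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "LIPID_CLASSES",
    "BLOCK_OF_CLASS",
    "DEFAULT_STANDARD_OF_CLASS",
    "LipidSpecies",
    "LipidParseError",
    "parse_lipid_name",
    "standard_for_class",
    "block_index",
]

#: Canonical class codes, in block order (PI last: it shares block 11 with
#: the class totals because it contributes a single species).
LIPID_CLASSES = (
    "Cer", "lysoPC", "lysoPE", "PA", "PC", "PE", "PG", "PS", "SM", "TG", "PI",
)

#: Block assignment: Cer=1 ... TG=10; PI rides in block 11 with class sums.
BLOCK_OF_CLASS = {
    "Cer": 1, "lysoPC": 2, "lysoPE": 3, "PA": 4, "PC": 5,
    "PE": 6, "PG": 7, "PS": 8, "SM": 9, "TG": 10, "PI": 11,
}

#: Internal standard per class.  Monoacyl glycerophospholipids share
#: PC(17:0/0:0); diacyl classes share PC(17:0/17:0) except ethanolamine
#: phospholipids, which use PE(17:0/17:0); ceramides use Cer(d18:1/17:0);
#: TG uses TG(17:0/17:0/17:0).  The SM assignment is not fixed by the
#: normalization convention this follows; PC(17:0/17:0) is the default and
#: can be overridden (see :func:`standard_for_class`).
DEFAULT_STANDARD_OF_CLASS = {
    "lysoPC": "PC(17:0/0:0)",
    "lysoPE": "PC(17:0/0:0)",
    "PA": "PC(17:0/17:0)",
    "PC": "PC(17:0/17:0)",
    "PG": "PC(17:0/17:0)",
    "PI": "PC(17:0/17:0)",
    "PS": "PC(17:0/17:0)",
    "PE": "PE(17:0/17:0)",
    "Cer": "Cer(d18:1/17:0)",
    "TG": "TG(17:0/17:0/17:0)",
    "SM": "PC(17:0/17:0)",
}

_CLASS_ALIASES = {c.lower(): c for c in LIPID_CLASSES}

_TERM_RE = re.compile(
    r"""^(?P<cls>[A-Za-z]+)\(
        (?P<body>[^()]*)
        \)$""",
    re.VERBOSE,
)
_CHAIN_RE = re.compile(r"^(?P<base>d)?(?P<c>\d+):(?P<d>\d+)(?P<ether>e)?$")


class LipidParseError(ValueError):
    """Raised when a shorthand lipid name cannot be parsed."""


@dataclass
class LipidSpecies:
    """Parsed identity of one lipid peak.

    ``peak_id`` is the unit of identity: result tables may list the same
    shorthand name twice for chromatographically distinct peaks.
    """

    peak_id: str
    raw_name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    ether: bool = False
    sphingoid_base: str | None = None
    chains: list[tuple[int, int]] | None = None
    ambiguous_with: list[tuple[str, int, int]] = field(default_factory=list)
    identified: bool = True
    # private rendering state so render() round-trips the raw string
    _class_token: str = ""
    _joiners: list[str] = field(default_factory=list)
    _alt_tokens: list[str] = field(default_factory=list)

    def render(self) -> str:
        """Re-render the shorthand name; inverse of :func:`parse_lipid_name`."""
        out = _render_term(
            self._class_token or self.lipid_class,
            self.sphingoid_base,
            self.chains,
            self.total_carbons,
            self.total_double_bonds,
            self.ether,
        )
        for joiner, tok in zip(self._joiners, self._alt_tokens):
            out += joiner + tok
        return out


def _render_term(cls_token, base, chains, carbons, dbonds, ether):
    if chains is not None:
        parts = []
        ch = list(chains)
        if base is not None:
            parts.append(base)
            bc, bd = _CHAIN_RE.match(base).group("c", "d")
            # base already contributes its chain; drop it from the list copy
            ch = ch[1:]
        parts += [f"{c}:{d}" for c, d in ch]
        body = "/".join(parts)
    else:
        body = f"{carbons}:{dbonds}"
        if ether:
            body += "e"
    return f"{cls_token}({body})"


def _split_terms(raw: str) -> tuple[list[str], list[str]]:
    """Split ``A(..)+B(..)`` / ``A(..)/B(..)`` on separators outside parens."""
    terms, joiners, depth, start = [], [], 0, 0
    for i, ch in enumerate(raw):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise LipidParseError(f"unbalanced ')' in {raw!r}")
        elif ch in "+/" and depth == 0:
            terms.append(raw[start:i])
            joiners.append(ch)
            start = i + 1
    if depth != 0:
        raise LipidParseError(f"unbalanced '(' in {raw!r}")
    terms.append(raw[start:])
    return terms, joiners


def _parse_term(term: str, raw: str):
    m = _TERM_RE.match(term.strip())
    if m is None:
        raise LipidParseError(
            f"cannot parse lipid term {term!r} in {raw!r}: expected CLASS(...)"
        )
    cls_token = m.group("cls")
    cls = _CLASS_ALIASES.get(cls_token.lower())
    if cls is None:
        raise LipidParseError(
            f"unknown lipid class {cls_token!r} in {raw!r}; "
            f"allowed: {', '.join(LIPID_CLASSES)}"
        )
    segs = m.group("body").split("/")
    chains: list[tuple[int, int]] = []
    base = None
    ether = False
    for i, seg in enumerate(segs):
        cm = _CHAIN_RE.match(seg.strip())
        if cm is None:
            raise LipidParseError(f"cannot parse chain token {seg!r} in {raw!r}")
        if cm.group("base"):
            if i != 0:
                raise LipidParseError(
                    f"sphingoid base {seg!r} must be first in {raw!r}"
                )
            base = seg.strip()
        if cm.group("ether"):
            ether = True
        chains.append((int(cm.group("c")), int(cm.group("d"))))
    carbons = sum(c for c, _ in chains)
    dbonds = sum(d for _, d in chains)
    resolved = len(segs) > 1  # a single C:D is a sum composition, not a chain
    return cls_token, cls, carbons, dbonds, ether, base, (chains if resolved else None)


def parse_lipid_name(
    raw_name: str, peak_id: str | None = None, identified: bool = True
) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Grammar: ``CLASS "(" [d]C:D[e] { "/" C:D }* ")"``, optionally joined by
    ``+`` or ``/`` to further ``CLASS(...)`` terms for ambiguous peaks.

    >>> sp = parse_lipid_name("SM(d18:0/24:0)")
    >>> sp.lipid_class, sp.total_carbons, sp.total_double_bonds
    ('SM', 42, 0)
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise LipidParseError(f"empty or non-string lipid name: {raw_name!r}")
    terms, joiners = _split_terms(raw_name.strip())
    tok, cls, c, d, ether, base, chains = _parse_term(terms[0], raw_name)
    alts = []
    alt_tokens = []
    for t in terms[1:]:
        atok, acls, ac, ad, aeth, abase, achains = _parse_term(t, raw_name)
        alts.append((acls, ac, ad))
        alt_tokens.append(
            _render_term(atok, abase, achains, ac, ad, aeth)
        )
    return LipidSpecies(
        peak_id=peak_id if peak_id is not None else raw_name,
        raw_name=raw_name,
        lipid_class=cls,
        total_carbons=c,
        total_double_bonds=d,
        ether=ether,
        sphingoid_base=base,
        chains=chains,
        ambiguous_with=alts,
        identified=identified,
        _class_token=tok,
        _joiners=joiners,
        _alt_tokens=alt_tokens,
    )


def standard_for_class(
    species: LipidSpecies | str, overrides: dict[str, str] | None = None
) -> str:
    """Internal-standard name used to normalize a species' intensities.

    ``overrides`` maps class code -> standard name and takes precedence over
    the defaults; use it e.g. to assign SM a dedicated standard.
    """
    cls = species if isinstance(species, str) else species.lipid_class
    table = dict(DEFAULT_STANDARD_OF_CLASS)
    if overrides:
        table.update(overrides)
    try:
        return table[cls]
    except KeyError:
        raise KeyError(
            f"no internal standard configured for lipid class {cls!r}"
        ) from None


def block_index(species: LipidSpecies | str) -> int:
    """Block number (1..11) of a species' primary class."""
    cls = species if isinstance(species, str) else species.lipid_class
    try:
        return BLOCK_OF_CLASS[cls]
    except KeyError:
        raise KeyError(f"unknown lipid class {cls!r}") from None
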