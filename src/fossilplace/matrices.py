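"""Discrete morphological character matrices and NEXUS round-tripping.

A cell holds a non-empty *set* of integer state codes: a singleton for an
observed state, the full state set for a missing ("?" or "-") entry, and
an intermediate set for polymorphism "(01)" / ambiguity "{01}" (the two
notations are treated identically; downstream parsimony and likelihood
handle them the same way).

NEXUS has no per-character state-space declaration (SYMBOLS is global),
so the writer embeds a ``[&statecounts=...]`` comment that the reader
honours; foreign files fall back to ``len(SYMBOLS)`` if declared, else
``max observed state + 1`` per character (floored at 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy

from .trees import Phylogeny, TaxonSet, normalize_label

__all__ = [
    "CharacterMatrix",
    "read_nexus_matrix",
    "write_nexus_matrix",
    "validate_compatibility",
    "CompatibilityReport",
]


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters table of state sets with per-character state counts."""

    taxa: TaxonSet
    rows: dict  # taxon label -> tuple of frozenset[int], one per character
    state_space: tuple  # k per character, each >= 2
    char_labels: Optional[tuple] = None

    def __post_init__(self):
        n = self.n_chars
        for label in self.taxa:
            if label not in self.rows:
                raise ValueError(f"matrix row missing for taxon {label!r}")
            row = self.rows[label]
            if len(row) != n:
                raise ValueError(
                    f"ragged matrix: taxon {label!r} has {len(row)} cells, expected {n}")
            for j, cell in enumerate(row):
                if not cell:
                    raise ValueError(f"empty state set at ({label!r}, char {j})")
                if not cell <= set(range(self.state_space[j])):
                    raise ValueError(
                        f"state(s) {sorted(cell)} outside 0..{self.state_space[j] - 1} "
                        f"at ({label!r}, char {j})")
        if any(k < 2 for k in self.state_space):
            raise ValueError("every character needs k >= 2 states")
        if self.char_labels is not None and len(self.char_labels) != n:
            raise ValueError("char_labels length mismatch")

    @property
    def n_chars(self) -> int:
        return len(self.state_space)

    def cell(self, taxon: str, char: int) -> frozenset:
        return self.rows[taxon][char]

    def is_missing(self, taxon: str, char: int) -> bool:
        return self.rows[taxon][char] == frozenset(range(self.state_space[char]))

    def column(self, char: int) -> dict:
        return {t: self.rows[t][char] for t in self.taxa}

    def select_chars(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Matrix with characters re-drawn in the given (possibly repeated)
        order — the bootstrap resampling primitive."""
        return CharacterMatrix(
            taxa=self.taxa,
            rows={t: tuple(self.rows[t][j] for j in indices) for t in self.taxa},
            state_space=tuple(self.state_space[j] for j in indices),
            char_labels=None if self.char_labels is None
            else tuple(self.char_labels[j] for j in indices),
        )

    def restrict_taxa(self, labels: Sequence[str]) -> "CharacterMatrix":
        keep = TaxonSet(labels)
        return CharacterMatrix(
            taxa=keep,
            rows={t: self.rows[t] for t in keep},
            state_space=self.state_space,
            char_labels=self.char_labels,
        )

    def __eq__(self, other) -> bool:
        return (isinstance(other, CharacterMatrix)
                and self.taxa == other.taxa
                and self.state_space == other.state_space
                and all(self.rows[t] == other.rows[t] for t in self.taxa)
                and self.char_labels == other.char_labels)


_STATECOUNTS_RE = re.compile(r"\[\s*&statecounts\s*=\s*([0-9\s]+)\]", re.IGNORECASE)
_CHARLABELS_RE = re.compile(r"\bCHARLABELS\s+(.*?);", re.IGNORECASE | re.DOTALL)


def _scan_duplicate_rows(source: str) -> None:
    m = re.search(r"\bMATRIX\b(.*?);", source, re.IGNORECASE | re.DOTALL)
    if not m:
        return
    seen: dict[str, int] = {}
    base_line = source[: m.start(1)].count("\n") + 1
    for off, line in enumerate(m.group(1).splitlines()):
        line = re.sub(r"\[.*?\]", "", line).strip()
        if not line:
            continue
        taxon = line.split()[0]
        if taxon in seen:
            raise ValueError(
                f"NEXUS parse error (line {base_line + off}): duplicate taxon row "
                f"{taxon!r} (first at line {seen[taxon]})")
        seen[taxon] = base_line + off


def read_nexus_matrix(source: str) -> CharacterMatrix:
    """Parse a NEXUS DATA/CHARACTERS block (DATATYPE=STANDARD) into a
    :class:`CharacterMatrix`.

    "?" and "-" become the full state set; "(..)" and "{..}" become the
    listed set.  Raises :class:`ValueError` naming the offending line on
    malformed input.
    """
    _scan_duplicate_rows(source)
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=source, schema="nexus")
    except Exception as exc:
        line = getattr(exc, "line_num", None)
        where = f" (line {line})" if line else ""
        raise ValueError(f"NEXUS parse error{where}: {exc}") from exc

    labels = [normalize_label(str(t.label)) for t in dm]
    taxa = TaxonSet(labels)
    seqs = {normalize_label(str(t.label)): dm[t] for t in dm}
    lengths = {lab: len(seq) for lab, seq in seqs.items()}
    n_chars = max(lengths.values(), default=0)
    ragged = [lab for lab, n in lengths.items() if n != n_chars]
    if ragged:
        raise ValueError(f"NEXUS parse error: ragged rows for taxa {ragged}")

    # raw per-cell digit sets; None marks fully-missing cells
    raw: dict[str, list] = {}
    for lab, seq in seqs.items():
        cells = []
        for st in seq:
            syms = [s.symbol for s in st.fundamental_states]
            if st.symbol in ("?", "-") or "-" in syms and len(syms) > 1:
                cells.append(None)
            elif syms == ["-"]:
                cells.append(None)
            else:
                try:
                    cells.append(frozenset(int(s) for s in syms))
                except ValueError as exc:
                    raise ValueError(
                        f"NEXUS parse error: non-digit state symbol {syms} "
                        f"for taxon {lab!r}") from exc
        raw[lab] = cells

    override = _STATECOUNTS_RE.search(source)
    declared = re.search(r'SYMBOLS\s*=\s*"([^"]*)"', source, re.IGNORECASE)
    state_space = []
    for j in range(n_chars):
        observed = set().union(*(raw[lab][j] or frozenset() for lab in labels))
        if override:
            counts = [int(x) for x in override.group(1).split()]
            if len(counts) != n_chars:
                raise ValueError("NEXUS parse error: statecounts comment length mismatch")
            k = counts[j]
        elif declared:
            k = max(len(declared.group(1)), 2)
        else:
            k = max(max(observed, default=0) + 1, 2)
        if observed and max(observed) >= k:
            raise ValueError(
                f"NEXUS parse error: character {j} has state {max(observed)} "
                f"outside declared alphabet of size {k}")
        state_space.append(k)

    rows = {
        lab: tuple(
            frozenset(range(state_space[j])) if cells[j] is None else cells[j]
            for j in range(n_chars))
        for lab, cells in raw.items()
    }

    char_labels = None
    lm = _CHARLABELS_RE.search(source)
    if lm:
        char_labels = tuple(normalize_label(x) for x in lm.group(1).split())
        if len(char_labels) != n_chars:
            char_labels = None

    return CharacterMatrix(taxa=taxa, rows=rows,
                           state_space=tuple(state_space), char_labels=char_labels)


def _format_cell(cell: frozenset, k: int) -> str:
    if cell == frozenset(range(k)):
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return "(" + "".join(str(s) for s in sorted(cell)) + ")"


def write_nexus_matrix(m: CharacterMatrix) -> str:
    """Serialize to NEXUS such that :func:`read_nexus_matrix` returns an
    equal matrix (round-trip identity)."""
    kmax = max(m.state_space)
    symbols = "".join(str(i) for i in range(kmax))
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={len(m.taxa)} NCHAR={m.n_chars};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "[&statecounts=" + " ".join(str(k) for k in m.state_space) + "]",
    ]
    if m.char_labels is not None:
        lines.append("CHARLABELS " + " ".join(
            l.replace(" ", "_") for l in m.char_labels) + ";")
    lines.append("MATRIX")
    width = max(len(t) for t in m.taxa) + 2
    for t in m.taxa:
        cells = "".join(_format_cell(c, k)
                        for c, k in zip(m.rows[t], m.state_space))
        lines.append(t.replace(" ", "_").ljust(width) + cells)
    lines += [";", "END;", ""]
    return "\n".join(lines)


@dataclass
class CompatibilityReport:
    """Outcome of checking a matrix against a backbone + fossil label."""

    ok: bool
    missing_from_matrix: set = field(default_factory=set)
    extra_in_matrix: set = field(default_factory=set)
    messages: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_compatibility(m: CharacterMatrix, backbone: Phylogeny,
                           fossil: str) -> CompatibilityReport:
    """Check that the matrix taxa equal the backbone leaves plus the fossil."""
    fossil = normalize_label(fossil)
    expected = set(backbone.leaf_labels()) | {fossil}
    got = set(m.taxa)
    missing = expected - got
    extra = got - expected
    msgs = []
    if fossil not in got:
        msgs.append(f"fossil {fossil!r} absent from matrix")
    if fossil in backbone.leaf_labels():
        msgs.append(f"fossil {fossil!r} already a backbone leaf")
    for t in sorted(missing - {fossil}):
        msgs.append(f"backbone leaf {t!r} absent from matrix")
    for t in sorted(extra):
        msgs.append(f"matrix taxon {t!r} not on backbone (and not the fossil)")
    ok = not missing and not extra and fossil not in backbone.leaf_labels()
    return CompatibilityReport(ok=ok, missing_from_matrix=missing,
                               extra_in_matrix=extra, messages=msgs)
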