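"""Degenerate primer construction, auditing, expansion and in-silico PCR.

A degenerate primer is a single synthesis pool written over the IUPAC
ambiguity codes plus inosine (``I``).  Primers are built from a
conserved alignment window: each column's set of observed bases maps to
the minimal IUPAC code covering it, and columns needing three or four
bases are preferentially written as inosine while an inosine budget
remains.  The budgets default to the study's operating rules: at most
four degenerate sites per primer and about two inosines.

Inosine is never placed in the 3'-terminal three positions — a
degenerate or universal base at the extension end impairs priming, and
the published primers all keep their 3' ends as literal bases.

Reverse primers are reported 5'->3' on the antisense strand (the
standard primer-table dialect): the reverse-complement of the window
consensus, with inosine complementing to inosine.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alphabets import (
    DNA_BASES,
    GAP,
    IUPAC_TO_SET,
    PRIMER_ALPHABET,
    SET_TO_IUPAC,
    revcomp,
)
from .errors import (
    AlphabetError,
    BudgetError,
    ExpansionError,
    FormatError,
    WindowError,
)
from .seqio import Alignment

DEFAULT_WINDOW = 20
MAX_DEGENERATE = 4
MAX_INOSINE = 2
THREE_PRIME_PROTECTED = 3  # no inosine in the last 3 positions


def _clean(seq: str) -> str:
    """Uppercase and strip whitespace (printed primers carry spaced groups)."""
    return re.sub(r"\s+", "", seq.upper())


def audit_primer(seq: str) -> tuple[int, int, int]:
    """Count degenerate sites and inosines; compute the expansion size.

    Returns ``(degenerate_site_count, inosine_count, expansion_size)``
    where a degenerate site is any non-ACGT symbol (inosine included)
    and the expansion size is the product of per-position base
    multiplicities, inosine counting as 4.
    """
    seq = _clean(seq)
    if not seq:
        raise FormatError("empty primer string")
    bad = {c for c in seq if c not in PRIMER_ALPHABET}
    if bad:
        raise AlphabetError(f"illegal primer characters: {sorted(bad)}")
    degenerate = sum(1 for c in seq if c not in DNA_BASES)
    inosines = seq.count("I")
    expansion = 1
    for c in seq:
        expansion *= len(IUPAC_TO_SET[c])
    return degenerate, inosines, expansion


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise FormatError(f"bad orientation {self.orientation!r}")
        audit_primer(self.sequence)  # validates alphabet

    @property
    def degenerate_site_count(self) -> int:
        return audit_primer(self.sequence)[0]

    @property
    def inosine_count(self) -> int:
        return audit_primer(self.sequence)[1]

    @property
    def expansion_size(self) -> int:
        return audit_primer(self.sequence)[2]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrimerPair:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    fwd_start: int | None = None  # design window starts, alignment coords
    rev_start: int | None = None
    annealing_temp: float | None = 57.0  # default screening temperature
    alt_annealing_temp: float | None = None  # metadata only

    def __post_init__(self) -> None:
        if self.forward.orientation != "forward":
            raise FormatError("first primer of a pair must be forward")
        if self.reverse.orientation != "reverse":
            raise FormatError("second primer of a pair must be reverse")


def _window_base_sets(
    aln: Alignment, start: int, w: int
) -> list[frozenset[str]]:
    if start < 0 or start + w > aln.length:
        raise WindowError(
            f"window [{start}, {start + w}) outside alignment of length {aln.length}"
        )
    sets: list[frozenset[str]] = []
    for j in range(start, start + w):
        col = aln.column(j)
        observed: set[str] = set()
        for base in col:
            if base == GAP:
                raise WindowError(f"gap in design window at column {j}")
            if base not in IUPAC_TO_SET:
                raise AlphabetError(f"non-DNA character {base!r} at column {j}")
            observed |= IUPAC_TO_SET[base]
        sets.append(frozenset(observed))
    return sets


def build_primer(
    aln: Alignment,
    start: int,
    w: int = DEFAULT_WINDOW,
    orientation: str = "forward",
    max_degenerate: int = MAX_DEGENERATE,
    max_inosine: int = MAX_INOSINE,
    name: str = "",
) -> DegeneratePrimer:
    """Build a degenerate primer from an alignment window.

    Per column the observed base set becomes the minimal IUPAC code;
    columns needing 3-4 bases become inosine while the inosine budget
    lasts (assigned 5'-first in the primer's own orientation, never in
    its 3'-terminal three positions), otherwise the 3/4-fold IUPAC
    code.  Raises :class:`BudgetError` when the number of non-ACGT
    positions would exceed ``max_degenerate``.
    """
    sets = _window_base_sets(aln, start, w)
    if orientation == "reverse":
        # Work in the primer's own 5'->3' direction: reverse the window
        # and complement each base set.
        sets = [frozenset(revcomp(b) for b in s) for s in reversed(sets)]
    elif orientation != "forward":
        raise FormatError(f"bad orientation {orientation!r}")

    n_degenerate = sum(1 for s in sets if len(s) > 1)
    if n_degenerate > max_degenerate:
        raise BudgetError(
            f"window needs {n_degenerate} degenerate sites "
            f"(budget {max_degenerate})"
        )
    symbols: list[str] = []
    inosines_used = 0
    n = len(sets)
    for pos, s in enumerate(sets):
        if len(s) == 1:
            symbols.append(next(iter(s)))
        elif (
            len(s) >= 3
            and inosines_used < max_inosine
            and pos < n - THREE_PRIME_PROTECTED
        ):
            symbols.append("I")
            inosines_used += 1
        else:
            symbols.append(SET_TO_IUPAC[s])
    return DegeneratePrimer(
        name=name or f"{orientation[:3]}_{start}",
        sequence="".join(symbols),
        orientation=orientation,
    )


def build_primer_pair(
    aln: Alignment,
    fwd_start: int,
    rev_start: int,
    w: int = DEFAULT_WINDOW,
    max_degenerate: int = MAX_DEGENERATE,
    max_inosine: int = MAX_INOSINE,
    name: str = "pair",
) -> PrimerPair:
    """Build the forward/reverse primer pair for a fragment candidate."""
    fwd = build_primer(
        aln, fwd_start, w, "forward", max_degenerate, max_inosine, f"{name}-1"
    )
    rev = build_primer(
        aln, rev_start, w, "reverse", max_degenerate, max_inosine, f"{name}-2"
    )
    return PrimerPair(forward=fwd, reverse=rev, fwd_start=fwd_start, rev_start=rev_start)


def expand_primer(primer: DegeneratePrimer | str, cap: int = 4096) -> list[str]:
    """All concrete ACGT sequences matching the degenerate pattern."""
    seq = _clean(primer.sequence if isinstance(primer, DegeneratePrimer) else primer)
    _, _, size = audit_primer(seq)
    if size > cap:
        raise ExpansionError(f"expansion size {size} exceeds cap {cap}")
    pools = [sorted(IUPAC_TO_SET[c]) for c in seq]
    return ["".join(p) for p in itertools.product(*pools)]


def primer_matches(pattern: str, base: str) -> bool:
    """IUPAC compatibility of one primer symbol with one template base.

    Inosine matches any base; an ambiguous template base never matches
    (primers bind real bases, so anything uncertain counts as a
    mismatch).
    """
    if base not in DNA_BASES:
        return False
    return base in IUPAC_TO_SET[pattern]


def _site_matches(
    pattern: str,
    template: str,
    pos: int,
    max_mismatch: int,
    exact_positions: Sequence[int],
) -> tuple[bool, int]:
    """Match a 5'->3' pattern against template[pos:pos+len(pattern)]."""
    mismatches = 0
    for k, sym in enumerate(pattern):
        ok = primer_matches(sym, template[pos + k])
        if not ok:
            if k in exact_positions:
                return False, mismatches
            mismatches += 1
            if mismatches > max_mismatch:
                return False, mismatches
    return True, mismatches


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int  # 0-based half-open on the template sense strand
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def in_silico_pcr(
    pair: PrimerPair,
    template: str,
    template_id: str = "template",
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    min_len: int = 100,
    max_len: int = 2000,
) -> list[Amplicon]:
    """Predict the amplicons a primer pair yields on a template.

    The forward primer is scanned along the sense strand; the reverse
    primer anneals to the sense strand, so its reverse complement is
    scanned as a sense-strand pattern whose *first* ``three_prime_exact``
    positions (the primer's 3' end) must match exactly.  A site matches
    when at most ``max_mismatch`` positions fail IUPAC compatibility.
    Every compatible site pair with product length within
    ``[min_len, max_len]`` is reported.
    """
    if min_len > max_len:
        raise FormatError(f"min_len {min_len} > max_len {max_len}")
    template = _clean(template)
    fwd = _clean(pair.forward.sequence)
    rev_on_sense = revcomp(_clean(pair.reverse.sequence))
    lf, lr = len(fwd), len(rev_on_sense)

    fwd_exact = range(lf - three_prime_exact, lf)
    rev_exact = range(0, three_prime_exact)

    fwd_sites = []
    for pos in range(len(template) - lf + 1):
        ok, mm = _site_matches(fwd, template, pos, max_mismatch, fwd_exact)
        if ok:
            fwd_sites.append((pos, mm))
    rev_sites = []
    for pos in range(len(template) - lr + 1):
        ok, mm = _site_matches(rev_on_sense, template, pos, max_mismatch, rev_exact)
        if ok:
            rev_sites.append((pos, mm))

    amplicons = []
    for fpos, fmm in fwd_sites:
        for rpos, rmm in rev_sites:
            end = rpos + lr
            length = end - fpos
            if fpos < rpos + lr and min_len <= length <= max_len and fpos <= rpos:
                amplicons.append(
                    Amplicon(
                        template_id=template_id,
                        start=fpos,
                        end=end,
                        fwd_mismatches=fmm,
                        rev_mismatches=rmm,
                    )
                )
    return amplicons


def parse_primer_name(name: str) -> str:
    """Orientation from the odd/even numbering convention (SA-1 -> forward)."""
    m = re.search(r"(\d+)\s*$", name)
    if not m:
        raise FormatError(f"primer name {name!r} has no trailing number")
    return "forward" if int(m.group(1)) % 2 == 1 else "reverse"
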