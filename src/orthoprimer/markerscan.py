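"""Sliding-window conservation scan and primer-site pair enumeration.

A multiple alignment of putative orthologs is scanned with a window of
20 nucleotides; for each start position the profile records how many
columns inside the window are identical in *all* rows (gap-free, and
unambiguous — primers bind real bases, so an IUPAC-ambiguous base never
counts as identical).  Candidate marker fragments are ordered pairs of
qualifying windows whose implied amplicon length — forward-window start
to reverse-window end — falls inside PCR-able bounds (350-850 bp by
default).  The study's manual "sifting" step is mechanised as this
length filter plus a ranked listing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alphabets import DNA_BASES
from .errors import AlignmentError, ConfigError
from .seqio import Alignment

DEFAULT_WINDOW = 20
DEFAULT_MIN_SEP = 350
DEFAULT_MAX_SEP = 850
N_RANGE = range(12, 19)  # conservation thresholds scanned by the study


@dataclass
class WindowProfile:
    """Per-start counts of all-rows-identical columns in a window."""

    counts: np.ndarray  # length = alignment length - w + 1
    w: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if ((self.counts < 0) | (self.counts > self.w)).any():
            raise ConfigError("window counts outside [0, w]")

    def __len__(self) -> int:
        return len(self.counts)

    def qualifying_starts(self, n: int) -> np.ndarray:
        return np.flatnonzero(self.counts >= n)


def identical_columns(aln: Alignment) -> np.ndarray:
    """Boolean per column: all rows carry the same unambiguous base.

    Gapped or ambiguous columns never count; for protein alignments the
    criterion is simply all rows equal and non-gap.
    """
    mat = aln.matrix()
    same = (mat == mat[0]).all(axis=0)
    if aln.kind == "dna":
        allowed = np.isin(mat[0], list(DNA_BASES))
    else:
        allowed = mat[0] != "-"
    return same & allowed


def window_profile(aln: Alignment, w: int = DEFAULT_WINDOW) -> WindowProfile:
    """Sliding-window identity profile of an alignment."""
    if aln.length < w:
        raise AlignmentError(
            f"alignment length {aln.length} shorter than window {w}"
        )
    if aln.kind == "protein":
        warnings.warn(
            "window scan on a protein alignment; thresholds are calibrated "
            "for nucleotides",
            stacklevel=2,
        )
    ident = identical_columns(aln).astype(int)
    counts = np.convolve(ident, np.ones(w, dtype=int), mode="valid")
    return WindowProfile(counts=counts, w=w)


@dataclass(frozen=True)
class FragmentCandidate:
    """A forward/reverse primer-site pair delimiting a candidate marker."""

    fwd_start: int
    rev_start: int
    n_level: int  # largest n in [12, 18] at which both windows qualify
    separation: int  # amplicon length: fwd-window start to rev-window end
    fwd_identity: int
    rev_identity: int
    w: int = DEFAULT_WINDOW


def _n_level(ci: int, cj: int, nmax: int = 18) -> int:
    return min(ci, cj, nmax)


def find_fragments(
    profile: WindowProfile,
    n: int,
    min_sep: int = DEFAULT_MIN_SEP,
    max_sep: int = DEFAULT_MAX_SEP,
    nmax: int = 18,
) -> list[FragmentCandidate]:
    """Enumerate window pairs conserved at level n within separation bounds.

    All ordered start pairs (i, j), i < j, with both window counts >= n
    and separation ``(j + w) - i`` inside ``[min_sep, max_sep]``.
    Sorted by descending n-level, then descending combined identity,
    then position, so the most promising fragment comes first.
    """
    if not 0 <= n <= profile.w:
        raise ConfigError(f"n={n} outside [0, {profile.w}]")
    if min_sep > max_sep:
        raise ConfigError(f"min_sep {min_sep} > max_sep {max_sep}")
    w = profile.w
    starts = profile.qualifying_starts(n)
    counts = profile.counts
    out: list[FragmentCandidate] = []
    for a, i in enumerate(starts):
        # separation = j + w - i ∈ [min_sep, max_sep]  =>  j ∈ [i+min_sep-w, i+max_sep-w]
        lo = np.searchsorted(starts, i + min_sep - w, side="left")
        hi = np.searchsorted(starts, i + max_sep - w, side="right")
        for j in starts[max(lo, a + 1) : hi]:
            out.append(
                FragmentCandidate(
                    fwd_start=int(i),
                    rev_start=int(j),
                    n_level=_n_level(int(counts[i]), int(counts[j]), nmax),
                    separation=int(j + w - i),
                    fwd_identity=int(counts[i]),
                    rev_identity=int(counts[j]),
                    w=w,
                )
            )
    out.sort(
        key=lambda c: (
            -c.n_level,
            -(c.fwd_identity + c.rev_identity),
            c.fwd_start,
            c.rev_start,
        )
    )
    return out


def max_separation_per_n(
    profile: WindowProfile, n_range: Iterable[int] = N_RANGE
) -> dict[int, int | None]:
    """Maximum primer-site separation at each conservation level.

    For each n, the largest ``(j + w) - i`` over all qualifying start
    pairs i < j, ignoring the PCR-able length sift; ``None`` when fewer
    than two windows qualify.
    """
    out: dict[int, int | None] = {}
    for n in n_range:
        starts = profile.qualifying_starts(n)
        if len(starts) < 2:
            out[n] = None
        else:
            out[n] = int(starts[-1] + profile.w - starts[0])
    return out


def revalidate_candidate(aln: Alignment, cand: FragmentCandidate) -> bool:
    """Recount both windows directly from the alignment (audit helper)."""
    ident = identical_columns(aln)
    fwd = int(ident[cand.fwd_start : cand.fwd_start + cand.w].sum())
    rev = int(ident[cand.rev_start : cand.rev_start + cand.w].sum())
    return fwd == cand.fwd_identity and rev == cand.rev_identity
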