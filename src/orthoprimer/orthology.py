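"""Reciprocal-best-hit orthology search with a paralog-exclusion filter.

The search chains best-hit lookups across three proteomes and accepts a
gene trio only when the chain returns to its starting gene (the
"triple boomerang" closure), then optionally fills a fourth slot by a
plain reciprocal-best-match test against a fourth proteome.  Similarity
is the exact Smith-Waterman local-alignment score (affine gaps;
BLOSUM62 for proteins, +5/-4 for DNA), standardised into a Z score
against scores obtained by shuffling the subject sequence.  To reduce
the chance of calling a recent paralog an ortholog, each search leg
also records the second-best Z, and a leg fails the paralog filter when
that second score exceeds 40% of the best or an absolute ceiling (156
by default).

Local alignment is computed by :class:`Bio.Align.PairwiseAligner`,
which implements the exact dynamic programme; this module owns the
statistics and the search logic on top of it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlphabetError, ConfigError, DegenerateDistributionError
from .seqio import GeneRecord, Proteome

DEFAULT_RATIO = 0.40
DEFAULT_ZMAX = 156.0
DEFAULT_Z_FLOOR = 3.0
DEFAULT_SHUFFLES = 100


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties."""

    kind: str = "protein"  # "protein" | "dna"
    matrix: str = "BLOSUM62"  # named matrix, or "match/mismatch" for DNA
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def aligner(self) -> Align.PairwiseAligner:
        return _make_aligner(self)


@lru_cache(maxsize=8)
def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    if scoring.kind == "protein":
        aln.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aln.match_score = scoring.match
        aln.mismatch_score = scoring.mismatch
    aln.open_gap_score = scoring.gap_open
    aln.extend_gap_score = scoring.gap_extend
    return aln


def protein_scoring(gap_open: float = -11.0, gap_extend: float = -1.0) -> Scoring:
    return Scoring(kind="protein", gap_open=gap_open, gap_extend=gap_extend)


def dna_scoring(
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -12.0,
    gap_extend: float = -2.0,
) -> Scoring:
    return Scoring(
        kind="dna", matrix="match/mismatch", match=match, mismatch=mismatch,
        gap_open=gap_open, gap_extend=gap_extend,
    )


def local_align_score(a: str, b: str, scoring: Scoring | None = None) -> float:
    """Score of the optimal local alignment of two sequences."""
    if not a or not b:
        raise AlphabetError("empty sequence")
    scoring = scoring or protein_scoring()
    aligner = scoring.aligner()
    if scoring.kind == "protein":
        alphabet = set(str(aligner.substitution_matrix.alphabet))
        bad = (set(a) | set(b)) - alphabet
        if bad:
            raise AlphabetError(
                f"residues {sorted(bad)} not in the {scoring.matrix} alphabet"
            )
    try:
        return float(aligner.score(a, b))
    except ValueError as exc:
        raise AlphabetError(str(exc)) from exc


def _pair_rng(seed: int, query_id: str, subject_id: str) -> np.random.Generator:
    """Deterministic RNG per (seed, query, subject), independent of search order."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(query_id.encode()), zlib.crc32(subject_id.encode())]
    )


def z_score(
    query: str,
    subject: str,
    scoring: Scoring | None = None,
    n_shuffles: int = DEFAULT_SHUFFLES,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Shuffle-standardised local alignment score.

    ``z = (raw - mean_shuffled) / sd_shuffled`` where the null scores
    come from ``n_shuffles`` random permutations of the subject's
    residues.  Deterministic for a fixed seed/rng.
    """
    if n_shuffles < 10:
        raise ConfigError("n_shuffles must be >= 10")
    if rng is None:
        if seed is None:
            raise ConfigError("z_score needs a seed or an rng")
        rng = np.random.default_rng(seed)
    scoring = scoring or protein_scoring()
    raw = local_align_score(query, subject, scoring)
    letters = np.array(list(subject))
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = local_align_score(query, "".join(rng.permutation(letters)), scoring)
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDistributionError(
            "shuffled-score distribution has zero spread"
        )
    return (raw - float(null.mean())) / sd


@dataclass(frozen=True)
class HitScore:
    query_id: str
    subject_id: str
    raw_score: float
    z: float


@dataclass(frozen=True)
class SearchLeg:
    query_id: str
    best: HitScore
    second: HitScore | None = None

    def __post_init__(self) -> None:
        if self.second is not None and self.best.z < self.second.z:
            raise ConfigError("best hit must have the highest z")


def best_hits(
    query: GeneRecord,
    target: Proteome,
    scoring: Scoring | None = None,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    z_floor: float = DEFAULT_Z_FLOOR,
) -> SearchLeg | None:
    """Best and second-best hit of a query in a target proteome.

    Hits are ranked by Z, ties broken by higher raw score then
    lexicographically smaller subject id; the second-best hit is the
    runner-up over *distinct* subject ids.  Returns ``None`` when no
    subject reaches ``z_floor`` (a best hit below the floor is treated
    as absent so that noise matches cannot close a boomerang).
    """
    if len(target) == 0:
        raise ConfigError("empty target proteome")
    scoring = scoring or protein_scoring()
    hits: list[HitScore] = []
    for rec in target:
        rng = _pair_rng(seed, query.id, rec.id)
        raw = local_align_score(query.seq, rec.seq, scoring)
        z = z_score(query.seq, rec.seq, scoring, n_shuffles, rng=rng)
        hits.append(HitScore(query.id, rec.id, raw, z))
    # Sort best-first: higher z, then higher raw, then lexicographic id.
    hits.sort(key=lambda h: (-h.z, -h.raw_score, h.subject_id))
    best = hits[0]
    if best.z < z_floor:
        return None
    second = hits[1] if len(hits) > 1 else None
    return SearchLeg(query_id=query.id, best=best, second=second)


@dataclass
class OrthologQuartet:
    """One putatively orthologous gene per species, with its search legs."""

    ids: list[str | None]  # slots for species 1-4; slot 4 may stay empty
    legs: list[SearchLeg] = field(default_factory=list)
    passed_paralog_filter: bool | None = None


def triple_boomerang(
    p1: Proteome,
    p2: Proteome,
    p3: Proteome,
    scoring: Scoring | None = None,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    z_floor: float = DEFAULT_Z_FLOOR,
) -> list[OrthologQuartet]:
    """Three-way best-hit closure over proteomes p1 -> p2 -> p3 -> p1.

    For each gene g1 of p1, follow the chain of best hits; the trio is
    accepted iff the final best hit in p1 is g1 itself.  Emitted
    quartets carry the three search legs; the fourth slot is empty.
    """
    scoring = scoring or protein_scoring()
    kw = dict(scoring=scoring, n_shuffles=n_shuffles, seed=seed, z_floor=z_floor)
    out: list[OrthologQuartet] = []
    for g1 in p1:
        leg1 = best_hits(g1, p2, **kw)
        if leg1 is None:
            continue
        g2 = p2[leg1.best.subject_id]
        leg2 = best_hits(g2, p3, **kw)
        if leg2 is None:
            continue
        g3 = p3[leg2.best.subject_id]
        leg3 = best_hits(g3, p1, **kw)
        if leg3 is None or leg3.best.subject_id != g1.id:
            continue
        out.append(
            OrthologQuartet(ids=[g1.id, g2.id, g3.id, None], legs=[leg1, leg2, leg3])
        )
    return out


def fourth_genome_check(
    quartet: OrthologQuartet,
    p4: Proteome,
    anchor: GeneRecord,
    anchor_proteome: Proteome,
    scoring: Scoring | None = None,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    z_floor: float = DEFAULT_Z_FLOOR,
) -> OrthologQuartet:
    """Fill the fourth slot by a reciprocal best match from the anchor.

    The anchor (one member of the accepted trio) queries the fourth
    proteome; the slot is filled iff the best hit's own best hit back in
    the anchor's proteome is the anchor gene.  Both reciprocal legs are
    retained on the quartet whenever they were computed, so the paralog
    filter sees them too.
    """
    kw = dict(scoring=scoring, n_shuffles=n_shuffles, seed=seed, z_floor=z_floor)
    leg4 = best_hits(anchor, p4, **kw)
    if leg4 is None:
        return quartet
    quartet.legs.append(leg4)
    g4 = p4[leg4.best.subject_id]
    leg5 = best_hits(g4, anchor_proteome, **kw)
    if leg5 is None:
        return quartet
    quartet.legs.append(leg5)
    if leg5.best.subject_id == anchor.id:
        quartet.ids[3] = g4.id
    return quartet


def paralog_filter(
    leg: SearchLeg,
    ratio: float = DEFAULT_RATIO,
    zmax: float = DEFAULT_ZMAX,
) -> bool:
    """True iff the leg passes the paralog-exclusion rule.

    Fails when a second-best hit exists and its Z exceeds ``ratio``
    times the best Z, or exceeds the absolute ceiling ``zmax``.
    """
    if leg.second is None:
        return True
    return not (leg.second.z > ratio * leg.best.z or leg.second.z > zmax)


def quartet_passes(
    quartet: OrthologQuartet,
    ratio: float = DEFAULT_RATIO,
    zmax: float = DEFAULT_ZMAX,
) -> bool:
    """A quartet passes only if every recorded search leg passes."""
    ok = all(paralog_filter(leg, ratio, zmax) for leg in quartet.legs)
    quartet.passed_paralog_filter = ok
    return ok


def find_ortholog_quartets(
    p1: Proteome,
    p2: Proteome,
    p3: Proteome,
    p4: Proteome,
    scoring: Scoring | None = None,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    z_floor: float = DEFAULT_Z_FLOOR,
    ratio: float = DEFAULT_RATIO,
    zmax: float = DEFAULT_ZMAX,
    anchor_slot: int = 2,
) -> list[OrthologQuartet]:
    """Full pipeline: boomerang closure, fourth-genome check, paralog filter.

    ``anchor_slot`` selects which member of each trio queries the fourth
    proteome (default slot 2, the member found in p3 — mirroring a
    search anchored on the best-annotated genome).
    """
    scoring = scoring or protein_scoring()
    kw = dict(scoring=scoring, n_shuffles=n_shuffles, seed=seed, z_floor=z_floor)
    quartets = triple_boomerang(p1, p2, p3, **kw)
    proteomes = [p1, p2, p3]
    for q in quartets:
        anchor_p = proteomes[anchor_slot]
        anchor = anchor_p[q.ids[anchor_slot]]
        fourth_genome_check(q, p4, anchor, anchor_p, **kw)
        quartet_passes(q, ratio=ratio, zmax=zmax)
    return quartets
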