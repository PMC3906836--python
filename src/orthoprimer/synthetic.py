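"""Seeded generators for every synthetic substrate the pipeline needs.

Four generators emulate the statistical structure the marker-discovery
pipeline assumes, each returning both the data and a truth table from
which the expected output of every downstream operation can be read
without re-deriving it:

* proteome quartets with planted 1:1 orthologs and, in some families, a
  recent within-species duplicate (the paralog the 40%/156 filter must
  exclude);
* nucleotide alignments of four species with two planted conserved
  primer windows flanking a PCR-able fragment, over a divergent
  background;
* alignments evolved site-independently on a known tree (Jukes-Cantor
  style uniform replacement), the substrate for parsimony-recovery
  experiments;
* strain panels of three diverged lineages with planted
  lineage-diagnostic SNPs and per-base Phred qualities, some below the
  trust threshold.

All generators are pure functions of their configuration (which
includes the seed): identical inputs give identical outputs.
Substitution processes are deliberately simple uniform-replacement
models — the pipeline under test is model-agnostic, and simple models
keep the truth tables exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .alphabets import DNA_BASES
from .errors import ConfigError
from .seqio import Alignment, GeneRecord, Proteome, QualityMask
from .alnstats import Tree, parse_newick, tree_leaves

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults are the desk-scale conditions the acceptance experiments
    run under: 20 ortholog families of 150-aa proteins at 70% pairwise
    identity between species, five of them carrying a 95%-similar
    within-species duplicate; 800-column marker alignments over a 40%-
    identity background with two 17/20-conserved windows delimiting a
    500-bp fragment; 16-strain panels in three lineages with 21 planted
    diagnostic SNPs over 600 sites.
    """

    seed: int = 0

    # proteome quartets
    n_families: int = 20
    protein_length: int = 150
    family_identity: float = 0.70  # target pairwise identity between species
    n_paralog_families: int = 5
    paralog_similarity: float = 0.95
    paralog_species: int = 1  # which species (0-based) carries the duplicates

    # marker alignments
    aln_length: int = 800
    bg_identity: float = 0.40
    window: int = 20
    fwd_start: int = 60
    rev_start: int = 540
    fwd_window_identity: int = 17
    rev_window_identity: int = 17

    # tree-evolved alignments
    subst_prob: float = 0.08
    tree_length: int = 300

    # strain panels
    n_strains: int = 16
    n_sites: int = 600
    n_snps: int = 21
    n_lineages: int = 3
    within_divergence: float = 0.0
    low_quality_fraction: float = 0.02
    q_trusted: tuple[int, int] = (41, 60)
    q_low: tuple[int, int] = (2, 39)

    def validate(self) -> None:
        for name in ("family_identity", "paralog_similarity", "bg_identity",
                     "within_divergence", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.subst_prob < 1.0:
            raise ConfigError("subst_prob must be in [0, 1)")
        if self.family_identity == 0.0:
            raise ConfigError("family_identity must be positive")


# ---------------------------------------------------------------------------
# proteome quartets


@dataclass(frozen=True)
class QuartetTruth:
    family: int
    ids: tuple[str, str, str, str]
    paralog_id: str | None
    expect_pass: bool  # pass/fail under the second-score paralog filter


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_proteome_quartet(
    cfg: SimConfig,
) -> tuple[list[Proteome], list[QuartetTruth]]:
    """Four proteomes with planted ortholog families and paralogs.

    Each family descends from a random ancestral protein; every species
    copy is mutated so that the *pairwise* identity between species is
    approximately ``family_identity`` (per-branch rate
    1 - sqrt(identity)).  Selected families additionally carry a
    within-species duplicate at ``paralog_similarity`` to that species'
    own copy.  The truth table predicts which families the paralog
    filter should keep.
    """
    cfg.validate()
    if cfg.n_paralog_families > cfg.n_families:
        raise ConfigError("more paralog families than families")
    rng = np.random.default_rng(cfg.seed)
    branch_rate = 1.0 - math.sqrt(cfg.family_identity)
    species = [f"sp{k + 1}" for k in range(4)]
    records: dict[str, list[GeneRecord]] = {s: [] for s in species}
    paralog_families = set(
        rng.choice(cfg.n_families, size=cfg.n_paralog_families, replace=False).tolist()
    ) if cfg.n_paralog_families else set()
    truths: list[QuartetTruth] = []
    for fam in range(cfg.n_families):
        ancestor = "".join(
            AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=cfg.protein_length)
        )
        ids = []
        copies = {}
        for sp in species:
            gid = f"{sp}_fam{fam:03d}"
            seq = _mutate_protein(ancestor, branch_rate, rng)
            records[sp].append(GeneRecord(id=gid, species=sp, seq=seq, kind="protein"))
            ids.append(gid)
            copies[sp] = seq
        paralog_id = None
        if fam in paralog_families:
            sp = species[cfg.paralog_species]
            paralog_id = f"{sp}_fam{fam:03d}p"
            dup = _mutate_protein(copies[sp], 1.0 - cfg.paralog_similarity, rng)
            records[sp].append(
                GeneRecord(id=paralog_id, species=sp, seq=dup, kind="protein")
            )
        truths.append(
            QuartetTruth(
                family=fam,
                ids=tuple(ids),
                paralog_id=paralog_id,
                expect_pass=paralog_id is None,
            )
        )
    proteomes = [Proteome(species=sp, records=records[sp]) for sp in species]
    return proteomes, truths


# ---------------------------------------------------------------------------
# marker alignments


@dataclass(frozen=True)
class MarkerTruth:
    fwd_start: int
    rev_start: int
    w: int
    fwd_identity: int
    rev_identity: int
    amplicon_length: int


def make_marker_alignment(cfg: SimConfig) -> tuple[Alignment, MarkerTruth]:
    """Four-species DNA alignment with two planted conserved windows.

    Background columns are identical in all rows with probability
    ``bg_identity`` and otherwise differ in exactly one row; the two
    planted windows are forced to their configured identity counts and
    are flanked by guard columns forced to differ, so a planted window
    is never silently extendable.  The implied amplicon runs from the
    forward-window start to the reverse-window end.
    """
    cfg.validate()
    w, L = cfg.window, cfg.aln_length
    if cfg.bg_identity >= 1.0:
        raise ConfigError(
            "bg_identity 1.0 makes everything conserved; no marker to find"
        )
    for name, start, ident in (
        ("fwd", cfg.fwd_start, cfg.fwd_window_identity),
        ("rev", cfg.rev_start, cfg.rev_window_identity),
    ):
        if not 0 <= start <= L - w:
            raise ConfigError(f"{name} window start {start} outside alignment")
        if not 0 <= ident <= w:
            raise ConfigError(f"{name} window identity {ident} outside [0, {w}]")
    if cfg.fwd_start + w > cfg.rev_start:
        raise ConfigError("planted windows overlap")
    rng = np.random.default_rng(cfg.seed)
    n_rows = 4
    cols: list[list[str]] = []

    def identical_col() -> list[str]:
        b = DNA_BASES[rng.integers(4)]
        return [b] * n_rows

    def variable_col() -> list[str]:
        b = DNA_BASES[rng.integers(4)]
        col = [b] * n_rows
        r = int(rng.integers(n_rows))
        others = [x for x in DNA_BASES if x != b]
        col[r] = others[rng.integers(3)]
        return col

    in_window = {}
    guards: set[int] = set()
    for start, ident in (
        (cfg.fwd_start, cfg.fwd_window_identity),
        (cfg.rev_start, cfg.rev_window_identity),
    ):
        variable = set(rng.choice(w, size=w - ident, replace=False).tolist())
        for k in range(w):
            in_window[start + k] = k in variable
        for g in (start - 1, start + w):
            if 0 <= g < L:
                guards.add(g)
    guards -= set(in_window)
    for j in range(L):
        if j in in_window:
            cols.append(variable_col() if in_window[j] else identical_col())
        elif j in guards:
            cols.append(variable_col())
        else:
            cols.append(identical_col() if rng.random() < cfg.bg_identity else variable_col())
    rows = ["".join(c[i] for c in cols) for i in range(n_rows)]
    aln = Alignment(
        names=[f"sp{i + 1}" for i in range(n_rows)], rows=rows, kind="dna"
    )
    truth = MarkerTruth(
        fwd_start=cfg.fwd_start,
        rev_start=cfg.rev_start,
        w=w,
        fwd_identity=cfg.fwd_window_identity,
        rev_identity=cfg.rev_window_identity,
        amplicon_length=cfg.rev_start + w - cfg.fwd_start,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# tree-evolved alignments


def _mutate_dna(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    for i in hits:
        others = [b for b in DNA_BASES if b != out[i]]
        out[i] = others[rng.integers(3)]
    return out


def evolve_on_tree(
    tree: Tree | str,
    length: int,
    subst_prob: float,
    seed: int,
) -> Alignment:
    """Evolve a random root sequence down a tree, site-independently.

    Every branch substitutes each site with probability ``subst_prob``
    to a uniformly chosen different base (Jukes-Cantor-like).  Leaf
    order in the output follows the tree's left-to-right leaf order.
    """
    if not 0.0 <= subst_prob < 1.0:
        raise ConfigError("subst_prob must be in [0, 1)")
    if isinstance(tree, str):
        tree = parse_newick(tree)
    rng = np.random.default_rng(seed)
    root = np.array([DNA_BASES[i] for i in rng.integers(4, size=length)], dtype="U1")
    names: list[str] = []
    rows: list[str] = []

    def walk(node: Tree, seq: np.ndarray) -> None:
        if isinstance(node, str):
            names.append(node)
            rows.append("".join(seq))
            return
        for child in node:
            walk(child, _mutate_dna(seq, subst_prob, rng))

    walk(tree, root)
    return Alignment(names=names, rows=rows, kind="dna")


# ---------------------------------------------------------------------------
# strain panels


@dataclass
class StrainPanel:
    aln: Alignment
    qualities: list[np.ndarray]
    mask: QualityMask
    truth: "StrainTruth"


@dataclass(frozen=True)
class StrainTruth:
    snp_positions: tuple[int, ...]  # planted lineage-diagnostic sites
    extra_variable: tuple[int, ...]  # within-lineage private mutations
    visible_variable: tuple[int, ...]  # variable after the Q40 mask
    lineage_of: tuple[int, ...]  # lineage index per strain


def make_strain_panel(cfg: SimConfig, qmin: int = 40) -> StrainPanel:
    """Strain panel of diverged lineages with planted SNPs and qualities.

    Planted SNPs are lineage-diagnostic (constant within each lineage),
    so parsimony on any tree grouping the lineages needs no homoplasy;
    optional within-lineage divergence adds private singletons.  A
    configured fraction of bases receives quality below Q40; the truth
    table records which variable sites remain visible once those bases
    are masked.
    """
    cfg.validate()
    if cfg.n_lineages < 2:
        raise ConfigError("need at least 2 lineages")
    if cfg.n_snps > cfg.n_sites:
        raise ConfigError("more SNPs than sites")
    rng = np.random.default_rng(cfg.seed)
    lineage_of = tuple(int(i % cfg.n_lineages) for i in range(cfg.n_strains))

    backbone = np.array(
        [DNA_BASES[i] for i in rng.integers(4, size=cfg.n_sites)], dtype="U1"
    )
    snp_positions = np.sort(
        rng.choice(cfg.n_sites, size=cfg.n_snps, replace=False)
    )
    # per SNP: allele per lineage, at least two distinct alleles
    lineage_alleles: dict[int, list[str]] = {}
    for pos in snp_positions:
        while True:
            alleles = [DNA_BASES[i] for i in rng.integers(4, size=cfg.n_lineages)]
            if len(set(alleles)) >= 2:
                break
        lineage_alleles[int(pos)] = alleles

    rows_arr = []
    extra_variable: set[int] = set()
    for i in range(cfg.n_strains):
        seq = backbone.copy()
        for pos, alleles in lineage_alleles.items():
            seq[pos] = alleles[lineage_of[i]]
        if cfg.within_divergence > 0:
            hits = np.flatnonzero(rng.random(cfg.n_sites) < cfg.within_divergence)
            for j in hits:
                others = [b for b in DNA_BASES if b != seq[j]]
                seq[j] = others[rng.integers(3)]
                if j not in lineage_alleles:
                    extra_variable.add(int(j))
        rows_arr.append(seq)

    qualities = []
    for i in range(cfg.n_strains):
        q = rng.integers(cfg.q_trusted[0], cfg.q_trusted[1] + 1, size=cfg.n_sites)
        low = rng.random(cfg.n_sites) < cfg.low_quality_fraction
        q[low] = rng.integers(cfg.q_low[0], cfg.q_low[1] + 1, size=int(low.sum()))
        qualities.append(q.astype(int))

    names = [f"strain{i + 1:02d}" for i in range(cfg.n_strains)]
    aln = Alignment(names=names, rows=["".join(r) for r in rows_arr], kind="dna")
    mask = QualityMask(
        names=names, trusted=[q >= qmin for q in qualities], qmin=qmin
    )
    visible = []
    for j in sorted(set(int(p) for p in snp_positions) | extra_variable):
        states = {
            rows_arr[i][j]
            for i in range(cfg.n_strains)
            if qualities[i][j] >= qmin
        }
        if len(states) >= 2:
            visible.append(j)
    truth = StrainTruth(
        snp_positions=tuple(int(p) for p in snp_positions),
        extra_variable=tuple(sorted(extra_variable)),
        visible_variable=tuple(visible),
        lineage_of=lineage_of,
    )
    return StrainPanel(aln=aln, qualities=qualities, mask=mask, truth=truth)
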