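"""Packaged study tables and their cross-consistency audit.

The package ships, as plain TSV with a sha256 manifest, the three
printed tables of the marker study it re-implements:

* **table1** — 25 yeast species x 14 gene fragments, a 0/1 indicator of
  which fragments were PCR-amplified and sequenced in which species,
  plus the printed per-species counts;
* **table2** — per gene fragment: number of species analysed (newly
  sequenced + published genomes), alignment length (amino acids),
  parsimony-informative characters and the minimum possible number of
  changes; the final row is the 18S rDNA alignment (nucleotides);
* **table3** — the 28 degenerate primers (14 pairs) with alternative
  annealing temperatures.  Odd-numbered names are forward primers,
  even-numbered reverse.

:func:`check_study_tables` recomputes every aggregate the study text
states from these tables and cross-checks rows against columns.  The
checks are reported, not enforced: one known one-off discrepancy exists
in the printed tables themselves (see the PDA1 column check), and the
report keeps it visible rather than hiding it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import IntegrityError
from .primers import audit_primer

GENE_CODES = "SA GI PG DE ME AT GC FS PA VM EC OL LT1 LT2".split()

N_TEST_SPECIES = 25  # species panel used for PCR screening
N_TOTAL_SPECIES = 43  # panel + published genomes in the phylogenetic matrix


@dataclass
class StudyTables:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame

    @property
    def indicator(self) -> pd.DataFrame:
        """Table 1 restricted to the 0/1 gene-by-species matrix."""
        return self.table1[GENE_CODES]

    @property
    def protein_genes(self) -> pd.DataFrame:
        """Table 2 without the 18S rDNA row."""
        return self.table2[self.table2["is_protein"] == 1]

    def primer_sequence(self, name: str) -> str:
        row = self.table3[self.table3["name"] == name]
        if row.empty:
            raise KeyError(name)
        return str(row.iloc[0]["sequence"]).replace(" ", "")


def _data_dir():
    return resources.files("orthoprimer") / "data"


def load_study_tables(verify: bool = True) -> StudyTables:
    """Load the packaged tables, verifying the checksum manifest."""
    d = _data_dir()
    manifest = json.loads((d / "manifest.json").read_text())
    frames = {}
    for fname in ("table1_species.tsv", "table2_genes.tsv", "table3_primers.tsv"):
        raw = (d / fname).read_bytes()
        if verify:
            digest = hashlib.sha256(raw).hexdigest()
            if digest != manifest.get(fname):
                raise IntegrityError(
                    f"fixture {fname} does not match its manifest checksum"
                )
        frames[fname] = pd.read_csv(
            d / fname, sep="\t", dtype={"cbs_id": str, "aat_celsius": str}
        )
    t1 = frames["table1_species.tsv"]
    t2 = frames["table2_genes.tsv"]
    t3 = frames["table3_primers.tsv"].fillna({"aat_celsius": ""})
    if len(t1) != 25 or len(t2) != 15 or len(t3) != 28:
        raise IntegrityError("fixture tables have unexpected shapes")
    return StudyTables(table1=t1, table2=t2, table3=t3)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (table convention)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class Check:
    name: str
    passed: bool
    observed: object
    expected: object

    def __str__(self) -> str:
        flag = "ok  " if self.passed else "FAIL"
        return f"[{flag}] {self.name}: observed {self.observed}, expected {self.expected}"


@dataclass
class ConsistencyReport:
    checks: list[Check] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add(self, name: str, observed, expected) -> None:
        self.checks.append(Check(name, observed == expected, observed, expected))

    @property
    def n_failed(self) -> int:
        return sum(not c.passed for c in self.checks)

    @property
    def all_passed(self) -> bool:
        return self.n_failed == 0

    def failures(self) -> list[Check]:
        return [c for c in self.checks if not c.passed]

    def __str__(self) -> str:
        lines = [str(c) for c in self.checks]
        lines.append(
            f"{len(self.checks)} checks, {self.n_failed} failed"
        )
        return "\n".join(lines)


def check_study_tables(tables: StudyTables | None = None) -> ConsistencyReport:
    """Recompute and cross-check every printed aggregate of the tables.

    Covers: the 257/73% sequencing totals, the 506/84% phylogenetic
    totals, the combined character/informative/min-change sums, row and
    column consistency between tables 1 and 2, the per-gene and
    per-species count ranges and means, and the primer degeneracy
    budget over table 3.
    """
    if tables is None:
        tables = load_study_tables()
    rep = ConsistencyReport()
    ind = tables.indicator
    prot = tables.protein_genes

    # --- totals stated in the study text ---
    total_seqs = int(ind.values.sum())
    rep.add("total sequences obtained (table1 indicator sum)", total_seqs, 257)
    pct = round_half_away(100 * total_seqs / (14 * N_TEST_SPECIES))
    rep.add("sequencing success percentage", pct, 73)

    total_protein = int(prot["n_species"].sum())
    rep.add("total protein-coding sequences analysed (table2 sum)", total_protein, 506)
    pct2 = round_half_away(100 * total_protein / (14 * N_TOTAL_SPECIES))
    rep.add("phylogenetic matrix fill percentage", pct2, 84)

    rep.add("combined characters (table2 lengths)", int(prot["aln_length"].sum()), 2587)
    rep.add(
        "combined parsimony-informative characters",
        int(prot["n_informative"].sum()),
        1087,
    )
    rep.add("combined minimum changes", int(prot["min_changes"].sum()), 4015)

    # --- table1 rows: indicator sums vs printed per-species counts ---
    row_sums = ind.sum(axis=1)
    for (_, row), rsum in zip(tables.table1.iterrows(), row_sums):
        rep.add(
            f"table1 row sum: {row['species']}", int(rsum), int(row["n_fragments"])
        )

    # --- table1 columns + published genomes vs table2 species counts ---
    col_sums = ind.sum(axis=0)
    for _, row in prot.iterrows():
        code = row["code"]
        pub = int(row["published_genomes"])
        rep.add(
            f"table1 column + published genomes: {code} ({row['gene']})",
            int(col_sums[code]) + pub,
            int(row["n_species"]),
        )

    # --- ranges and means stated in the study text ---
    rep.add("min species newly sequenced per gene", int(col_sums.min()), 12)
    rep.add("max species newly sequenced per gene", int(col_sums.max()), 24)
    rep.add(
        "mean species newly sequenced per gene (rounded)",
        round_half_away(float(col_sums.mean())),
        18,
    )
    rep.add("min fragments per species", int(row_sums.min()), 4)
    rep.add("max fragments per species", int(row_sums.max()), 14)
    rep.add(
        "mean fragments per species (rounded)",
        round_half_away(float(row_sums.mean())),
        10,
    )

    # --- primer degeneracy budget over table 3 ---
    audits = [
        audit_primer(tables.primer_sequence(n)) for n in tables.table3["name"]
    ]
    max_deg = max(a[0] for a in audits)
    rep.add("max degenerate sites over the 28 primers", max_deg, 4)
    rep.summary = {
        "total_sequences": total_seqs,
        "pct_sequenced": pct,
        "total_protein_sequences": total_protein,
        "pct_protein": pct2,
        "combined_characters": int(prot["aln_length"].sum()),
        "combined_informative": int(prot["n_informative"].sum()),
        "combined_min_changes": int(prot["min_changes"].sum()),
        "species_per_gene": (int(col_sums.min()), int(col_sums.max())),
        "fragments_per_species": (int(row_sums.min()), int(row_sums.max())),
        "max_degenerate_sites": max_deg,
        "inosine_outliers": [
            name
            for name, a in zip(tables.table3["name"], audits)
            if a[1] > 2
        ],
    }
    return rep
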