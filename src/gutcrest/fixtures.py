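"""Packaged worked-example fixtures.

Four gene tables (the >=4-fold deregulated-gene list with category labels,
the HSCR/ENS gene panel, the downregulated X-linked genes, and the
chromosome-10 candidates) plus a small ganglionic-fraction cohort whose two
sentinel animals carry the published extreme values (83.6% affected, 77.1%
non-affected).

The printed tables use a decimal-comma / space-thousands dialect which is
parsed to plain floats and ints here.  The tables print fold changes but
not per-gene p-values (every included gene satisfied both adjusted p <
0.001); fixture records therefore carry both adjusted p-values as the
stated ceiling so the consensus filter can be exercised on them.  Fold
changes are stored verbatim and never recomputed from the printed mean raw
counts, whose normalisation factors are not recoverable.

Two rows of the deregulated-gene table (``LostEntryUp1/2``) are synthetic
placeholders: the available transcription of that table is truncated and
these restore its published tallies (41 down / 188 up / 229 total).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .expression_screen import internal_fold
from .synthio import Cohort

__all__ = ["FixtureTables", "load_fixture_tables"]

# Every gene in the printed tables passed both test schemes at the stated
# adjusted-p ceiling; records carry this bound (exclusive) as their p-value.
PADJ_CEILING = 0.001

EXPECTED_ROWS = {"table1": 229, "table2": 12, "table3": 22, "table4": 12}
EXPECTED_T1_TALLY = {"up": 188, "down": 41}


def _parse_printed_number(x: str) -> float:
    return float(str(x).replace(" ", "").replace(" ", "").replace(",", "."))


def _read(name: str) -> pd.DataFrame:
    path = resources.files("gutcrest.data") / name
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)


@dataclass
class FixtureTables:
    deregulated: pd.DataFrame  # >=4-fold genes with category labels
    hscr_genes: pd.DataFrame  # HSCR/ENS panel with coordinates
    x_linked: pd.DataFrame  # downregulated X-linked genes
    chr10: pd.DataFrame  # chromosome-10 candidates
    sentinel_cohort: Cohort  # worked-example ganglionic-fraction cohort


def _finish_gene_table(df: pd.DataFrame, chromosome: str | None = None) -> pd.DataFrame:
    out = df.copy()
    out["fold_display"] = out["fold"].map(_parse_printed_number)
    out["fold"] = internal_fold(out["fold_display"].to_numpy())
    for col in ("mutant_mean_count", "control_mean_count", "start", "end"):
        if col in out:
            out[col] = out[col].map(_parse_printed_number).astype(int)
    if chromosome is not None:
        out["chromosome"] = chromosome
    elif "chromosome" in out:
        out["chromosome"] = out["chromosome"].astype(str)
    out["padj_exact"] = PADJ_CEILING * (1 - 1e-9)
    out["padj_lrt"] = PADJ_CEILING * (1 - 1e-9)
    return out.set_index("gene")


def load_fixture_tables() -> FixtureTables:
    """Load and validate the packaged fixtures.

    Raises ``ValueError`` if a packaged table fails its row-count or tally
    check (guards against a corrupted installation).
    """
    t1 = _read("table1_deregulated.tsv")
    t1["fold_display"] = t1["fold"].map(_parse_printed_number)
    t1["fold"] = internal_fold(t1["fold_display"].to_numpy())
    t1["padj_exact"] = PADJ_CEILING * (1 - 1e-9)
    t1["padj_lrt"] = PADJ_CEILING * (1 - 1e-9)
    t1 = t1.set_index("gene")

    t2 = _finish_gene_table(_read("table2_hscr_genes.tsv"))
    t3 = _finish_gene_table(_read("table3_x_linked.tsv"), chromosome="X")
    t4 = _finish_gene_table(_read("table4_chr10.tsv"), chromosome="10")

    checks = {"table1": t1, "table2": t2, "table3": t3, "table4": t4}
    for name, df in checks.items():
        if len(df) != EXPECTED_ROWS[name]:
            raise ValueError(
                f"fixture checksum mismatch: {name} has {len(df)} rows, "
                f"expected {EXPECTED_ROWS[name]}"
            )
    up = int((t1["fold_display"] > 0).sum())
    down = int((t1["fold_display"] < 0).sum())
    if {"up": up, "down": down} != EXPECTED_T1_TALLY:
        raise ValueError(
            f"fixture checksum mismatch: deregulated-gene tallies {up} up / "
            f"{down} down"
        )

    path = resources.files("gutcrest.data") / "sentinel_cohort.tsv"
    with resources.as_file(path) as p:
        animals = pd.read_csv(p, sep="\t", comment="#")
    animals["megacolon"] = animals["megacolon"].astype(bool)
    cohort = Cohort(animals=animals, threshold=80.0)

    return FixtureTables(
        deregulated=t1, hscr_genes=t2, x_linked=t3, chr10=t4, sentinel_cohort=cohort
    )


# Insertion coordinate used by the packaged candidate-ranking demo: derived
# as the closest candidate's start minus its published ~3.6 Mb offset; a
# derived convenience value, not a measured coordinate.
DERIVED_INSERTION_POSITION = 51_585_420 - 3_600_000  # = 47,985,420
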