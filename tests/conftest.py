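import pytest

from ryr2apms.tables_io import (
    ProteinGroup,
    ProteinGroupTable,
    PsmRow,
    PsmTable,
)

CHANNELS = ("anti_bait", "igg", "beads")
CONDITIONS = ("WT", "S2814A", "S2814D")


def make_pg(pid, anti, igg, beads, gene="", unique=5, description="", **flags):
    return ProteinGroup(
        protein_id=pid,
        gene_symbol=gene,
        unique_peptides=unique,
        lfq={"anti_bait": float(anti), "igg": float(igg), "beads": float(beads)},
        description=description,
        **flags,
    )


def make_table(rows, provenance="test"):
    table = ProteinGroupTable(channels=CHANNELS, rows=tuple(rows), provenance=provenance)
    table.validate()
    return table


def make_psm_row(pid, wt, a, d, peptides=5, gene=""):
    return PsmRow(
        protein_id=pid,
        gene_symbol=gene,
        psm={"WT": int(wt), "S2814A": int(a), "S2814D": int(d)},
        peptides=peptides,
    )


def make_psm_table(rows, bait_id):
    table = PsmTable(conditions=CONDITIONS, rows=tuple(rows), bait_id=bait_id)
    table.validate()
    return table


@pytest.fixture
def maxquant_tsv(tmp_path):
    """A 3-row MaxQuant-style proteinGroups export (one row flagged reverse)."""
    header = "\t".join([
        "Majority protein IDs", "Gene names", "Razor + unique peptides",
        "LFQ intensity RyR2", "LFQ intensity IgG", "LFQ intensity Beads",
        "Reverse", "Potential contaminant", "Only identified by site",
    ])
    lines = [
        header,
        "E9Q401;Q9ERA1\tRyr2\t48\t1.2e9\t350000\t410000\t\t\t",
        "P12345\tAifm1\t7\t900000\t200000\t0\t\t\t",
        "REV__P99999\tXxx1\t3\t100000\t100000\t100000\t+\t\t",
    ]
    path = tmp_path / "proteinGroups.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def psm_tsv(tmp_path):
    """A 2-row Proteome Discoverer-style PSM export including the bait."""
    header = "\t".join([
        "Accession", "Gene Symbol", "# Peptides",
        "# PSMs WT", "# PSMs S2814A", "# PSMs S2814D",
    ])
    lines = [
        header,
        "E9Q401\tRyr2\t40\t300\t290\t310",
        "P12345\tAifm1\t6\t30\t45\t12",
    ]
    path = tmp_path / "psm.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
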