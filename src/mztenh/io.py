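"""Plain-text readers and writers for the pipeline's tables.

Regions travel as BED6 (name = region id, score = 0, strand = "."),
fragments as BED3 per sample, methylation as a 4-column tab table, TSS
and expression tables as TSV, and Ct tables as CSV. Every writer has a
matching reader and the pair round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": regions["chrom"], "start": regions["start"],
        "end": regions["end"], "name": regions["region_id"],
        "score": 0, "strand": "."})
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLS)
    return pd.DataFrame({"region_id": bed["name"], "chrom": bed["chrom"],
                         "start": bed["start"], "end": bed["end"]})


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end"])


def write_methylation(table: pd.DataFrame, path) -> None:
    table.reset_index()[["region_id", "embryo", "egg", "sperm"]].to_csv(
        path, sep="\t", index=False)


def read_methylation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("region_id")


def write_tsv(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_ct_table(table: pd.DataFrame, path) -> None:
    table[["embryo_id", "group", "primer", "rep", "ct"]].to_csv(
        path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_sample_manifest(path) -> pd.DataFrame:
    """CSV manifest: path, mark, replicate, stage, is_control,
    spike_pairs."""
    manifest = pd.read_csv(path)
    required = {"path", "mark", "replicate", "stage"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    return manifest


def read_jaspar_pfm(path):
    """Read a JASPAR-style .pfm/.jaspar file into a Pwm.

    Accepts both the bare 4-row count format and the bracketed
    ``A [ 1 2 3 ]`` layout.
    """
    import numpy as np

    from .association import Pwm

    lines = Path(path).read_text().strip().splitlines()
    motif_id = "motif"
    rows = []
    for line in lines:
        if line.startswith(">"):
            motif_id = line[1:].split()[0]
            continue
        cleaned = line.replace("[", " ").replace("]", " ")
        parts = cleaned.split()
        if parts and parts[0].upper() in "ACGT":
            parts = parts[1:]
        rows.append([float(x) for x in parts])
    counts = np.asarray(rows)
    if counts.shape[0] != 4:
        raise ValueError("expected 4 base rows in PWM file")
    return Pwm.from_counts(motif_id, counts, pseudo=0.01)
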