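"""Primary transcription-unit lengths from annotation.

The window model needs one number per gene: the genomic span of its
primary TU in kb. That table is a two-column TSV (gene_id,
tu_length_kb); it can be produced from a GTF/GFF with
:func:`tu_lengths_from_gtf`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from zgakit.schedule import TranscriptionUnit


def read_tu_lengths(path: str | Path) -> dict[str, float]:
    """Read a gene_id / tu_length_kb TSV into a mapping."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "tu_length_kb"} - set(df.columns)
    if missing:
        raise ValueError(f"TU-length file missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id in TU-length file: {dup!r}")
    units = {}
    for row in df.itertuples():
        tu = TranscriptionUnit(str(row.gene_id), float(row.tu_length_kb))
        units[tu.gene_id] = tu.tu_length_kb
    return units


def tu_lengths_from_gtf(gtf_path: str | Path) -> pd.DataFrame:
    """Derive per-gene primary-TU lengths (kb) from a GTF/GFF.

    The primary TU is taken as the genomic span of the gene feature
    (end - start + 1). Returns a DataFrame with columns gene_id,
    tu_length_kb.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        rows.append(
            {"gene_id": gid, "tu_length_kb": (gene.end - gene.start + 1) / 1000.0}
        )
    if not rows:
        raise ValueError(f"no gene features found in {gtf_path}")
    return pd.DataFrame(rows)
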