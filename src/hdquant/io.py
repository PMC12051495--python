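"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are TSV/CSV; single-cell matrices can arrive as matrix-market
triplets with side annotation files or as a dense TSV for small data;
sequences use FASTA.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "read_sc_mtx",
    "read_sc_dense",
    "read_bulk_tsv",
    "write_panel_tsv",
    "write_fasta",
    "read_de_table",
]


def read_sc_mtx(matrix_path, genes_path, annotation_path) -> ad.AnnData:
    """Assemble an AnnData from an MTX matrix (genes x cells) plus side files.

    ``genes_path`` is a one-column gene list; ``annotation_path`` is a TSV
    with columns cell_id, fine_type, condition (one row per matrix column).
    """
    from scipy.io import mmread

    X = mmread(str(matrix_path)).tocsr().T  # cells x genes
    genes = pd.read_csv(genes_path, header=None)[0].astype(str).tolist()
    obs = pd.read_csv(annotation_path, sep="\t")
    need = {"cell_id", "fine_type", "condition"}
    if not need <= set(obs.columns):
        raise ValueError(f"annotation must have columns {sorted(need)}")
    if X.shape != (len(obs), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(obs)} cells x {len(genes)} genes"
        )
    obs = obs.rename(columns={"fine_type": "cell_type"}).set_index("cell_id")
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))


def read_sc_dense(path, annotation_path) -> ad.AnnData:
    """Dense genes x cells TSV plus a cell annotation TSV, for small fixtures."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    obs = pd.read_csv(annotation_path, sep="\t").rename(
        columns={"fine_type": "cell_type"}).set_index("cell_id")
    obs.index = obs.index.astype(str)
    mat.columns = mat.columns.astype(str)
    missing = set(mat.columns) ^ set(obs.index)
    if missing:
        raise ValueError(f"cells mismatch between matrix and annotation: {sorted(missing)[:5]}")
    return ad.AnnData(X=mat[obs.index].T.to_numpy(), obs=obs,
                      var=pd.DataFrame(index=mat.index.astype(str)))


def read_bulk_tsv(path) -> pd.DataFrame:
    """Genes x samples TPM table with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_panel_tsv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def write_fasta(sequences: pd.DataFrame, path) -> None:
    """Write a (gene, sequence) frame as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(row.sequence), id=str(row.gene), description="")
               for row in sequences.itertuples()]
    SeqIO.write(records, str(path), "fasta")


def read_de_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-gene DE statistics TSV.

    ``column_map`` translates the file's column names onto the expected
    gene/log2fc/pvalue trio, accommodating exports whose headers differ.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    need = {"gene", "log2fc", "pvalue"}
    if not need <= set(df.columns):
        raise ValueError(f"DE table must provide columns {sorted(need)} "
                         "(use column_map to rename)")
    return df
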