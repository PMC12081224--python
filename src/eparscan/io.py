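"""Plain-text I/O: TSV tables, FASTA junction sets, Newick trees.

All tabular formats are tab-separated with a header row; genomic
coordinates are 1-based inclusive (GRCh38 convention) and element
coordinates 1-based from the distal end.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import BranchSNP, HaplogroupTree

__all__ = [
    "write_intensity_matrix", "read_intensity_matrix",
    "write_marker_metadata", "read_marker_metadata",
    "write_table", "read_table",
    "write_fasta", "read_fasta",
    "read_tree", "write_tree",
    "load_config",
]


def write_intensity_matrix(
    path, intensities: pd.DataFrame, sex: pd.Series
) -> None:
    out = intensities.copy()
    out.insert(0, "sex", sex.loc[out.index])
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_intensity_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    sex = frame.pop("sex")
    return frame, sex


def write_marker_metadata(path, markers: pd.DataFrame) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_marker_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, table: pd.DataFrame, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def read_tree(newick_path, snp_table_path=None) -> HaplogroupTree:
    """Load a haplogroup tree from Newick plus an optional SNP map TSV.

    The SNP table needs columns snp_id, branch, ancestral, derived.
    """
    newick = Path(newick_path).read_text()
    snps = None
    if snp_table_path is not None:
        table = pd.read_csv(snp_table_path, sep="\t")
        snps = {
            row.snp_id: BranchSNP(row.snp_id, row.branch, row.ancestral, row.derived)
            for row in table.itertuples()
        }
    return HaplogroupTree.from_newick(newick, snps)


def write_tree(newick_path, tree: HaplogroupTree, snp_table_path=None) -> None:
    Path(newick_path).write_text(tree.to_newick() + "\n")
    if snp_table_path is not None:
        rows = [
            (s.snp_id, s.branch, s.ancestral, s.derived)
            for s in tree.snp_map.values()
        ]
        pd.DataFrame(
            rows, columns=["snp_id", "branch", "ancestral", "derived"]
        ).to_csv(snp_table_path, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle) or {}
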