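"""Plain-text readers/writers for the pipeline's standard inputs and outputs.

Gene lists are one symbol per line; networks are 2-column TSV edge lists;
expression is a genes x samples TSV with a separate sample/stage TSV;
incidence matrices are exported as MatrixMarket plus gene/set index TSVs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio

from .hypergraph import Hypergraph
from .model import RiskScores

__all__ = [
    "read_gene_list",
    "write_gene_list",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "write_expression",
    "read_stages",
    "write_stages",
    "write_scores",
    "export_incidence",
]


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (optional header detected by a 'gene'-like first row)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"gene1", "source", "from", "u", "gene_a"}:
        df = df.iloc[1:]
    return [(str(u), str(v)) for u, v in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene1\tgene2\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV matrix, first column = gene symbol."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t")


def read_stages(path: str | Path) -> np.ndarray:
    """Two-column TSV (sample, stage) or one stage code per line."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    col = df.iloc[:, -1]
    if not np.issubdtype(col.dtype, np.number):
        col = pd.to_numeric(col.iloc[1:])  # skip header row
    return col.to_numpy(dtype=int)


def write_stages(samples: Sequence[str], stage: Sequence[int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s, st in zip(samples, stage):
            fh.write(f"{s}\t{int(st)}\n")


def write_scores(scores: RiskScores, path: str | Path, seed: int | None = None) -> None:
    """Gene / risk_score / rank TSV, ranked descending (ties by symbol)."""
    order = sorted(range(len(scores.genes)), key=lambda i: (-scores.risk[i], scores.genes[i]))
    with Path(path).open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("gene\trisk_score\trank\n")
        for rank, i in enumerate(order, start=1):
            fh.write(f"{scores.genes[i]}\t{scores.risk[i]:.6g}\t{rank}\n")


def export_incidence(hg: Hypergraph, prefix: str | Path) -> None:
    """Write <prefix>.mtx (sparse incidence), <prefix>.genes.tsv, <prefix>.sets.tsv."""
    prefix = Path(prefix)
    sio.mmwrite(str(prefix) + ".mtx", hg.incidence)
    with Path(str(prefix) + ".genes.tsv").open("w") as fh:
        fh.write("index\tgene\n")
        for i, g in enumerate(hg.genes):
            fh.write(f"{i}\t{g}\n")
    with Path(str(prefix) + ".sets.tsv").open("w") as fh:
        fh.write("index\tset_id\tcollection\tdegree\n")
        deg = np.asarray(hg.incidence.sum(axis=0)).ravel().astype(int)
        for i, (s, tag) in enumerate(zip(hg.set_ids, hg.collection_tags)):
            fh.write(f"{i}\t{s}\t{tag or ''}\t{deg[i]}\n")
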