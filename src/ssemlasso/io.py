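"""Expression tables, gene sets, rankings and network serialization.

The on-disk expression format is a plain tab-delimited matrix: header row of
sample identifiers, first column of gene identifiers, numeric body.  Gene
sets are newline-delimited identifier lists ('#' comments and blank lines
ignored).  Trained networks are stored as a sparse edge list plus a per-gene
training-mean table.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCompendium",
    "GeneSet",
    "read_expression_table",
    "write_expression_table",
    "read_gene_set",
    "append_experiments",
    "write_ranking_table",
    "read_ranking_table",
    "write_network",
    "read_network",
]


@dataclass
class ExpressionCompendium:
    """A genes x samples matrix of normalized, log-scale expression values.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns.  Row/column order is meaningful and preserved.
    metadata:
        Optional free-text annotations per sample (condition label,
        replicate id, exposure time, concentration ...), keyed by sample id.
    """

    data: pd.DataFrame
    metadata: dict[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if cols.has_duplicates:
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            bad = np.argwhere(~np.isfinite(values.astype(float)))[0]
            raise ValueError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        """The p x n value matrix."""
        return self.data.to_numpy(dtype=float)

    @property
    def p(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    def column(self, sample: str) -> pd.Series:
        """Expression vector of one sample, indexed by gene."""
        if sample not in self.data.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.data[sample].astype(float)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def read_expression_table(path: str | Path) -> ExpressionCompendium:
    """Parse a tab-delimited expression matrix.

    The first header field (corner cell) is ignored; remaining header fields
    are sample ids.  Errors report the offending row/column coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        if not sample_ids:
            raise ValueError(f"{path}: header row contains no sample identifiers")
        seen: set[str] = set()
        for s in sample_ids:
            if s in seen:
                raise ValueError(f"{path}: duplicate sample identifier {s!r}")
            seen.add(s)
        n = len(sample_ids)
        genes: list[str] = []
        gene_seen: set[str] = set()
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n + 1:
                raise ValueError(
                    f"{path}: row {lineno} has {len(fields) - 1} values, expected {n}"
                )
            gid = fields[0]
            if gid in gene_seen:
                raise ValueError(f"{path}: duplicate gene identifier {gid!r} (row {lineno})")
            gene_seen.add(gid)
            genes.append(gid)
            try:
                rows.append(np.array([float(v) for v in fields[1:]], dtype=float))
            except ValueError:
                for col, v in enumerate(fields[1:]):
                    try:
                        float(v)
                    except ValueError:
                        raise ValueError(
                            f"{path}: non-numeric cell {v!r} at row {lineno}, "
                            f"column {sample_ids[col]!r}"
                        ) from None
                raise
    if not genes:
        raise ValueError(f"{path}: no data rows")
    frame = pd.DataFrame(np.vstack(rows), index=genes, columns=sample_ids)
    return ExpressionCompendium(frame)


def write_expression_table(compendium: ExpressionCompendium, path: str | Path) -> None:
    """Write a compendium as a tab-delimited matrix at full float precision."""
    if compendium.n == 0:
        raise ValueError("refusing to write a compendium with no samples")
    path = Path(path)
    buf = _io.StringIO()
    buf.write("gene\t" + "\t".join(compendium.samples) + "\n")
    values = compendium.values
    for gid, row in zip(compendium.genes, values):
        buf.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    path.write_text(buf.getvalue())


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited gene list; '#' comments and blanks ignored."""
    path = Path(path)
    members: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        members.add(line)
    if not members:
        raise ValueError(f"{path}: gene set is empty after filtering")
    return GeneSet(name=name or path.stem, members=frozenset(members))


def append_experiments(
    base: ExpressionCompendium, extra: ExpressionCompendium
) -> ExpressionCompendium:
    """Append experiment columns to a training compendium.

    Genes are aligned by identifier; the base compendium's row order wins.
    The appended table must cover exactly the base gene universe and bring
    no colliding sample ids.  Base values are unchanged in the result.
    """
    base_genes = set(base.genes)
    extra_genes = set(extra.genes)
    if base_genes != extra_genes:
        missing = sorted(base_genes - extra_genes)
        surplus = sorted(extra_genes - base_genes)
        parts = []
        if missing:
            parts.append(f"missing genes: {missing}")
        if surplus:
            parts.append(f"unknown genes: {surplus}")
        raise ValueError("gene universe mismatch; " + "; ".join(parts))
    collisions = sorted(set(base.samples) & set(extra.samples))
    if collisions:
        raise ValueError(f"sample identifier collision: {collisions}")
    aligned = extra.data.loc[base.data.index]
    merged = pd.concat([base.data, aligned], axis=1)
    metadata = dict(base.metadata)
    metadata.update(extra.metadata)
    return ExpressionCompendium(merged, metadata=metadata)


def write_ranking_table(ranking, path: str | Path) -> None:
    """Write a ranking as TSV: gene, residual, abs_residual, rank, percentile.

    Rows are sorted by rank ascending (rank 1 first).
    """
    from .evaluation import rank_percentile

    p = len(ranking.genes)
    frame = pd.DataFrame(
        {
            "gene": ranking.genes,
            "residual": ranking.residuals,
            "abs_residual": ranking.abs_residual,
            "rank": ranking.rank,
        }
    )
    frame["percentile"] = [rank_percentile(r, p) for r in frame["rank"]]
    frame = frame.sort_values("rank", kind="stable")
    frame.to_csv(path, sep="\t", index=False)


def read_ranking_table(path: str | Path) -> pd.DataFrame:
    """Read a ranking TSV back into a DataFrame indexed by gene."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "rank"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: not a ranking table (columns {list(frame.columns)})")
    return frame.set_index("gene")


def write_network(net, out_dir: str | Path) -> None:
    """Serialize a trained network: sparse edge list + per-gene means.

    ``edges.tsv`` holds (target_gene, source_gene, coefficient) for every
    nonzero entry of B-hat; ``means.tsv`` holds the training means used to
    center test vectors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = net.genes
    rows_i, cols_j = np.nonzero(net.B_hat)
    edges = pd.DataFrame(
        {
            "target_gene": [genes[i] for i in rows_i],
            "source_gene": [genes[j] for j in cols_j],
            "coefficient": net.B_hat[rows_i, cols_j],
        }
    )
    edges.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
    means = pd.DataFrame({"gene": genes, "train_mean": net.train_means})
    means.to_csv(out_dir / "means.tsv", sep="\t", index=False)
    if getattr(net, "lasso_report", None) is not None:
        net.lasso_report.to_csv(out_dir / "lasso_report.tsv", sep="\t", index=False)


def read_network(in_dir: str | Path):
    """Load a network serialized by :func:`write_network`."""
    from .training import InteractionNetwork

    in_dir = Path(in_dir)
    means = pd.read_csv(in_dir / "means.tsv", sep="\t", dtype={"gene": str})
    genes = list(means["gene"])
    index = {g: i for i, g in enumerate(genes)}
    p = len(genes)
    B = np.zeros((p, p))
    edges = pd.read_csv(in_dir / "edges.tsv", sep="\t", dtype={"target_gene": str, "source_gene": str})
    for tgt, src, coef in edges.itertuples(index=False):
        B[index[tgt], index[src]] = coef
    report_path = in_dir / "lasso_report.tsv"
    report = pd.read_csv(report_path, sep="\t") if report_path.exists() else None
    return InteractionNetwork(
        genes=genes,
        B_hat=B,
        train_means=means["train_mean"].to_numpy(dtype=float),
        lasso_report=report,
    )


def gene_set_to_file(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene set as a newline-delimited list (sorted for determinism)."""
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")
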