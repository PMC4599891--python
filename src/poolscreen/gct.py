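"""Minimal GCT 1.2 and CLS readers/writers.

GCT 1.2: two header lines (``#1.2`` then ``<n_genes>\t<n_samples>``)
followed by a TSV with ``Name``, ``Description`` and one column per
sample. CLS (categorical): ``<n> <k> 1`` / ``# <names...>`` / space-
separated integer labels.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["read_gct", "write_gct", "read_cls", "write_cls"]


def write_gct(matrix: pd.DataFrame, path, descriptions=None) -> None:
    """Write a genes × samples DataFrame as GCT 1.2."""
    desc = descriptions if descriptions is not None else ["na"] * len(matrix)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for (name, row), d in zip(matrix.iterrows(), desc):
            fh.write(str(name) + "\t" + str(d) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        n_genes, n_samples = map(int, fh.readline().split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"GCT header promises {(n_genes, n_samples)}, file has {df.shape}"
        )
    return df.astype(float)


def write_cls(labels: pd.Series, path, class_names=("train0", "train1")) -> None:
    vals = labels.astype(int)
    with open(path, "w") as fh:
        fh.write(f"{len(vals)} {vals.nunique()} 1\n")
        fh.write("# " + " ".join(class_names) + "\n")
        fh.write(" ".join(map(str, vals.to_numpy())) + "\n")


def read_cls(path) -> list[int]:
    with open(path) as fh:
        fh.readline()
        fh.readline()
        return [int(x) for x in fh.readline().split()]
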