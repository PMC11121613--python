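"""Plain-TSV readers/writers shared by all stages.

Matrices are features x samples, first column the feature id; the
sample-to-group map lives in its own two-column table so that the same
matrix can serve several contrasts.
"""

from __future__ import annotations

import pandas as pd


def write_matrix(matrix: pd.DataFrame, path, id_name: str = "feature_id") -> None:
    matrix.rename_axis(id_name).to_csv(path, sep="\t")


def read_matrix(path, id_name: str = "feature_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0]).rename_axis(id_name)


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").rename_axis("sample_id").to_csv(path, sep="\t")


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id")["group"]


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
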