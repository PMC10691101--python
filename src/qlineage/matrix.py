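"""Binary mutation matrices over {0, 1, missing}.

Rows are cells, columns are mutations.  Internally entries are int8 with
-1 encoding a missing value; on disk the dialect is TSV with a header row
of mutation ids, a first column of cell labels, and '?' for missing.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["MutationMatrix", "MISSING_CODE"]

MISSING_CODE = -1


class MutationMatrix:
    """An n-cells x k-mutations matrix with entries in {0, 1, missing}."""

    def __init__(self, data: np.ndarray, cell_labels: Sequence[str],
                 mutation_ids: Optional[Sequence[str]] = None):
        data = np.asarray(data, dtype=np.int8)
        if data.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        n, k = data.shape
        if len(cell_labels) != n:
            raise ValueError("cell label count does not match row count")
        if len(set(cell_labels)) != n:
            raise ValueError("cell labels must be unique")
        if mutation_ids is None:
            mutation_ids = [f"m{j}" for j in range(k)]
        if len(mutation_ids) != k:
            raise ValueError("mutation id count does not match column count")
        bad = set(np.unique(data)) - {0, 1, MISSING_CODE}
        if bad:
            raise ValueError(f"entries must be 0, 1 or missing; found {sorted(bad)}")
        self.data = data
        self.cell_labels = list(cell_labels)
        self.mutation_ids = list(mutation_ids)

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.data.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.data[:, j]

    def missing_fraction(self) -> float:
        return float(np.mean(self.data == MISSING_CODE))

    # -- TSV dialect ---------------------------------------------------------

    def to_tsv(self, path, comment: Optional[str] = None) -> None:
        with open(path, "w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("cell\t" + "\t".join(self.mutation_ids) + "\n")
            for i, cell in enumerate(self.cell_labels):
                row = ["?" if v == MISSING_CODE else str(int(v)) for v in self.data[i]]
                fh.write(cell + "\t" + "\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
        data = df.replace("?", str(MISSING_CODE)).astype(np.int8).to_numpy()
        return cls(data, [str(c) for c in df.index], [str(m) for m in df.columns])

    def subset_cells(self, labels: Sequence[str]) -> "MutationMatrix":
        idx = [self.cell_labels.index(l) for l in labels]
        return MutationMatrix(self.data[idx], list(labels), self.mutation_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MutationMatrix)
            and self.cell_labels == other.cell_labels
            and self.mutation_ids == other.mutation_ids
            and np.array_equal(self.data, other.data)
        )
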