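"""Protein-by-sample intensity matrix with a two-group design."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CONTROL = "control"
CASE = "MCT"


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a tab-separated table, ignoring '#'-prefixed comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


@dataclass
class IntensityMatrix:
    """Label-free quantification intensities, proteins x samples.

    Parameters
    ----------
    intensities
        Non-negative linear-scale intensities; the index holds unique
        protein accessions, the columns hold sample identifiers.  Zeros
        encode non-detection (dropout).
    design
        Series mapping each sample identifier to its group label; exactly
        two groups must be present.
    control, case
        Which design label is the reference group and which the treated
        (MCT) group.
    """

    intensities: pd.DataFrame
    design: pd.Series
    control: str = CONTROL
    case: str = CASE

    def __post_init__(self) -> None:
        if not self.intensities.index.is_unique:
            raise ValueError("protein accessions must be unique")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = set(self.intensities.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        self.design = self.design.loc[list(self.intensities.columns)]
        groups = set(self.design.unique())
        if groups != {self.control, self.case}:
            raise ValueError(
                f"design must contain exactly the groups "
                f"{{{self.control!r}, {self.case!r}}}, got {sorted(groups)}"
            )

    def group_columns(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    @property
    def control_columns(self) -> list[str]:
        return self.group_columns(self.control)

    @property
    def case_columns(self) -> list[str]:
        return self.group_columns(self.case)

    @property
    def accessions(self) -> pd.Index:
        return self.intensities.index

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.intensities.copy(), self.design.copy(), self.control, self.case
        )

    def subset(self, accessions) -> "IntensityMatrix":
        return IntensityMatrix(
            self.intensities.loc[list(accessions)], self.design, self.control, self.case
        )

    @classmethod
    def from_tsv(
        cls,
        matrix_path: str | Path,
        design_path: str | Path,
        control: str = CONTROL,
        case: str = CASE,
    ) -> "IntensityMatrix":
        """Load from a matrix TSV (first column = accession) and a design TSV
        with columns ``sample`` and ``group``."""
        mat = read_tsv(matrix_path, index_col=0)
        design = read_tsv(design_path)
        if not {"sample", "group"} <= set(design.columns):
            raise ValueError("design file needs 'sample' and 'group' columns")
        series = design.set_index("sample")["group"]
        return cls(mat, series, control=control, case=case)

    def to_tsv(self, matrix_path: str | Path, design_path: str | Path) -> None:
        out = self.intensities.copy()
        out.index.name = "accession"
        out.to_csv(matrix_path, sep="\t")
        design = pd.DataFrame({"sample": self.design.index, "group": self.design.values})
        write_tsv(design, design_path)
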