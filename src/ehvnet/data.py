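"""Domain types and CSV readers/writers.

Three tables flow through the pipeline:

* :class:`ExperimentCounts` — tidy flow-cytometry-style enumerations, one row
  per (host, challenge, replicate, timepoint) with cell and virion
  concentrations per mL.  The reserved challenge label :data:`CONTROL` marks
  the uninfected control wells of each host strain.
* :class:`StrainMetadata` — identity, isolation year and ocean of origin for
  every host and virus strain.
* :class:`InfectionMatrix` — the labelled binary hosts x viruses lysis
  matrix (1 = lysis, 0 = no lysis) that the network statistics consume.

All concentrations are stored as per-mL floats; no unit conversion is ever
applied silently.  CSV dialect is fixed: comma separated, UTF-8, ``.``
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

#: Reserved challenge_id for uninfected control wells.
CONTROL = "CONTROL"

COUNT_COLUMNS = [
    "host_id",
    "challenge_id",
    "replicate",
    "timepoint_h",
    "cell_conc",
    "virus_conc",
]

METADATA_COLUMNS = ["strain_id", "role", "isolation_year", "origin"]


class ValidationError(ValueError):
    """A table violated one of the domain invariants."""


@dataclass(frozen=True)
class StrainMetadata:
    """Strain identity table: id, role (host/virus), isolation year, origin."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata is missing columns {missing}")
        bad_role = set(df["role"].unique()) - {"host", "virus"}
        if bad_role:
            raise ValidationError(f"unknown roles {sorted(bad_role)}")
        for role, sub in df.groupby("role"):
            dup = sub["strain_id"][sub["strain_id"].duplicated()]
            if not dup.empty:
                raise ValidationError(
                    f"duplicated {role} strain_id(s): {sorted(dup.unique())}"
                )
        years = pd.to_numeric(df["isolation_year"], errors="coerce")
        known = years.dropna()
        bad = known[(known < 1900) | (known > 2100)]
        if not bad.empty:
            ids = df.loc[bad.index, "strain_id"].tolist()
            raise ValidationError(f"implausible isolation_year for {ids}")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def ids(self, role: str) -> list[str]:
        sub = self.table[self.table["role"] == role]
        return sub["strain_id"].tolist()

    def year_of(self, strain_id: str) -> float:
        sub = self.table[self.table["strain_id"] == strain_id]
        if sub.empty:
            raise KeyError(strain_id)
        y = sub["isolation_year"].iloc[0]
        return float(y) if pd.notna(y) else float("nan")


@dataclass(frozen=True)
class ExperimentCounts:
    """Tidy cell/virion concentration table for the two-timepoint design."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"counts table is missing columns {missing}")
        df = df.copy()
        for col in ("cell_conc", "virus_conc", "timepoint_h"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str) != "")
            if col != "virus_conc" and coerced.isna().any():
                row = df[coerced.isna()].iloc[0]
                raise ValidationError(
                    f"non-numeric {col} for (host={row['host_id']}, "
                    f"challenge={row['challenge_id']}, replicate={row['replicate']})"
                )
            if bad.any():
                row = df[bad].iloc[0]
                raise ValidationError(
                    f"non-numeric {col} for (host={row['host_id']}, "
                    f"challenge={row['challenge_id']}, replicate={row['replicate']})"
                )
            df[col] = coerced
        df["replicate"] = df["replicate"].astype(int)

        for col in ("cell_conc",):
            vals = df[col]
            if not np.isfinite(vals).all() or (vals < 0).any():
                row = df[~np.isfinite(vals) | (vals < 0)].iloc[0]
                raise ValidationError(
                    f"negative or non-finite {col} for (host={row['host_id']}, "
                    f"challenge={row['challenge_id']}, replicate={row['replicate']})"
                )
        vp = df["virus_conc"]
        bad_vp = vp.notna() & (~np.isfinite(vp) | (vp < 0))
        if bad_vp.any():
            row = df[bad_vp].iloc[0]
            raise ValidationError(
                f"negative or non-finite virus_conc for (host={row['host_id']}, "
                f"challenge={row['challenge_id']}, replicate={row['replicate']})"
            )
        missing_vp = vp.isna() & (df["challenge_id"] != CONTROL)
        if missing_vp.any():
            row = df[missing_vp].iloc[0]
            raise ValidationError(
                f"missing virus_conc in inoculated well (host={row['host_id']}, "
                f"challenge={row['challenge_id']}, replicate={row['replicate']})"
            )

        # every (host, challenge, replicate) series needs both timepoints
        tps = sorted(df["timepoint_h"].unique())
        if len(tps) != 2:
            raise ValidationError(
                f"expected exactly two timepoints, found {tps}"
            )
        grouped = df.groupby(["host_id", "challenge_id", "replicate"])["timepoint_h"]
        counts = grouped.nunique()
        incomplete = counts[counts != 2]
        if not incomplete.empty:
            host, chall, rep = incomplete.index[0]
            raise ValidationError(
                f"missing timepoint for (host={host}, challenge={chall}, "
                f"replicate={rep})"
            )
        # every host needs at least one control series
        has_control = df.groupby("host_id")["challenge_id"].apply(
            lambda s: (s == CONTROL).any()
        )
        orphans = has_control[~has_control]
        if not orphans.empty:
            raise ValidationError(
                f"host {orphans.index[0]} has no {CONTROL} series"
            )
        # canonical row order so downstream results ignore input ordering
        df = df.sort_values(
            ["host_id", "challenge_id", "replicate", "timepoint_h"]
        ).reset_index(drop=True)
        object.__setattr__(self, "table", df)

    # -- convenience views -------------------------------------------------
    @property
    def hosts(self) -> list[str]:
        return sorted(self.table["host_id"].unique())

    @property
    def viruses(self) -> list[str]:
        ch = self.table["challenge_id"].unique()
        return sorted(c for c in ch if c != CONTROL)

    @property
    def timepoints(self) -> tuple[float, float]:
        t = sorted(self.table["timepoint_h"].unique())
        return (float(t[0]), float(t[1]))

    def series(self, host: str, challenge: str) -> pd.DataFrame:
        sub = self.table[
            (self.table["host_id"] == host)
            & (self.table["challenge_id"] == challenge)
        ]
        if sub.empty:
            raise KeyError(
                f"no rows for (host={host}, challenge={challenge})"
            )
        return sub

    def replicate_mean(
        self, host: str, challenge: str, column: str, timepoint_h: float
    ) -> float:
        """Mean of ``column`` over replicates at one timepoint."""
        sub = self.series(host, challenge)
        vals = sub.loc[sub["timepoint_h"] == timepoint_h, column]
        return float(vals.mean())


@dataclass(frozen=True)
class InfectionMatrix:
    """Labelled binary hosts x viruses matrix: 1 = lysis, 0 = no lysis."""

    hosts: tuple[str, ...]
    viruses: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError("matrix must be two-dimensional")
        if values.shape != (len(self.hosts), len(self.viruses)):
            raise ValidationError(
                f"shape {values.shape} does not match "
                f"{len(self.hosts)} hosts x {len(self.viruses)} viruses"
            )
        if len(set(self.hosts)) != len(self.hosts):
            raise ValidationError("duplicated host label")
        if len(set(self.viruses)) != len(self.viruses):
            raise ValidationError("duplicated virus label")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValidationError(
                f"non-binary entry at (host={self.hosts[bad[0]]}, "
                f"virus={self.viruses[bad[1]]})"
            )
        object.__setattr__(self, "hosts", tuple(self.hosts))
        object.__setattr__(self, "viruses", tuple(self.viruses))
        object.__setattr__(self, "values", values.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def fill(self) -> int:
        """Number of 1s (interactions)."""
        return int(self.values.sum())

    def transpose(self) -> "InfectionMatrix":
        return InfectionMatrix(self.viruses, self.hosts, self.values.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.hosts), columns=list(self.viruses)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InfectionMatrix":
        return cls(
            tuple(str(i) for i in frame.index),
            tuple(str(c) for c in frame.columns),
            frame.to_numpy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InfectionMatrix):
            return NotImplemented
        return (
            self.hosts == other.hosts
            and self.viruses == other.viruses
            and np.array_equal(self.values, other.values)
        )


# -- CSV IO ---------------------------------------------------------------

def read_counts(path: str | Path) -> ExperimentCounts:
    """Read and validate a tidy counts CSV."""
    df = pd.read_csv(
        path,
        dtype={"host_id": str, "challenge_id": str},
        float_precision="round_trip",
    )
    return ExperimentCounts(df)


def write_counts(counts: ExperimentCounts, path: str | Path) -> None:
    counts.table.to_csv(path, index=False)


def read_metadata(path: str | Path) -> StrainMetadata:
    df = pd.read_csv(path, dtype={"strain_id": str, "role": str, "origin": str})
    return StrainMetadata(df)


def write_metadata(metadata: StrainMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, index=False)


def read_matrix(path: str | Path) -> InfectionMatrix:
    """Read a matrix CSV: virus ids in the header, host ids in column one."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(",")[1:]
    seen: set[str] = set()
    for label in header:
        if label in seen:
            raise ValidationError(f"duplicated virus label {label!r}")
        seen.add(label)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in header]
    if df.index.duplicated().any():
        raise ValidationError(
            f"duplicated host label {df.index[df.index.duplicated()][0]!r}"
        )
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        i, j = np.argwhere(~np.isin(vals, (0, 1)))[0]
        raise ValidationError(
            f"non-binary cell {vals[i, j]!r} at "
            f"(row={df.index[i]}, column={df.columns[j]})"
        )
    return InfectionMatrix.from_frame(df)


def write_matrix(matrix: InfectionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)
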