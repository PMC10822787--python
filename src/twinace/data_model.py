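"""Domain types for twin/singleton phenotype data and long-format file I/O.

The in-memory container is a thin wrapper around a :class:`pandas.DataFrame`
with one row per individual and columns ``family_id, zygosity, sex,
birth_order, age, <measure...>``.  Families belong to one of seven
sex-by-zygosity groups: monozygotic and dizygotic male/female pairs (MZM, DZM,
MZF, DZF), opposite-sex dizygotic pairs (DZOS), and male/female non-twin
singletons (SGM, SGF).  Missing phenotype values are NaN throughout; the
likelihood machinery treats them structurally (observed-entry marginals),
never numerically.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DuplicateRecordError, FormatError

__all__ = [
    "ZygosityGroup",
    "TwinRecord",
    "TwinDataset",
    "PAIR_GROUPS",
    "SINGLETON_GROUPS",
    "ALL_GROUPS",
    "read_dataset",
    "write_dataset",
    "pair_arrays",
]

PAIR_GROUPS = ("MZM", "DZM", "MZF", "DZF", "DZOS")
SINGLETON_GROUPS = ("SGM", "SGF")
ALL_GROUPS = PAIR_GROUPS + SINGLETON_GROUPS

#: sex required of every member, for single-sex groups
GROUP_SEX = {
    "MZM": "male",
    "DZM": "male",
    "MZF": "female",
    "DZF": "female",
    "SGM": "male",
    "SGF": "female",
}

MALE, FEMALE = "male", "female"
META_COLUMNS = ["family_id", "zygosity", "sex", "birth_order", "age"]


class ZygosityGroup(str, enum.Enum):
    """Sex-by-zygosity group code."""

    MZM = "MZM"
    DZM = "DZM"
    MZF = "MZF"
    DZF = "DZF"
    DZOS = "DZOS"
    SGM = "SGM"
    SGF = "SGF"

    @property
    def is_pair(self) -> bool:
        return self.value in PAIR_GROUPS

    @property
    def is_singleton(self) -> bool:
        return self.value in SINGLETON_GROUPS

    @property
    def member_sex(self) -> str | None:
        """Required member sex, or None for the mixed-sex DZOS group."""
        return GROUP_SEX.get(self.value)


@dataclass(frozen=True)
class TwinRecord:
    """One individual: identity, covariates and phenotype values."""

    family_id: str
    member_index: int  # birth order; 1 for singletons
    sex: str
    age: float
    measures: Mapping[str, float] = field(default_factory=dict)


class TwinDataset:
    """Individual-level phenotype rows organised into families and groups.

    Parameters
    ----------
    df
        One row per individual with the meta columns plus measure columns.
        Row order is preserved and reproduced on write.
    measure_names
        Ordered list of measure columns to expose.
    validate
        Run structural validation (uniqueness, group arity, sex consistency).
    """

    def __init__(self, df: pd.DataFrame, measure_names: Iterable[str], *, validate: bool = True):
        measure_names = list(measure_names)
        missing = [c for c in META_COLUMNS + measure_names if c not in df.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        df = df[META_COLUMNS + measure_names].copy()
        df["family_id"] = df["family_id"].astype(str)
        df["zygosity"] = df["zygosity"].astype(str)
        df["sex"] = df["sex"].astype(str)
        df["birth_order"] = df["birth_order"].astype(int)
        df["age"] = df["age"].astype(float)
        for m in measure_names:
            df[m] = pd.to_numeric(df[m], errors="coerce").astype(float)
        df = df.reset_index(drop=True)
        self._df = df
        self.measure_names = measure_names
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        df = self._df
        bad = ~df["zygosity"].isin(ALL_GROUPS)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"unknown zygosity code {df['zygosity'].iloc[i]!r} at row {i}"
            )
        bad_sex = ~df["sex"].isin((MALE, FEMALE))
        if bad_sex.any():
            i = int(np.flatnonzero(bad_sex.to_numpy())[0])
            raise FormatError(f"unknown sex {df['sex'].iloc[i]!r} at row {i}")
        if not df["birth_order"].isin((1, 2)).all():
            raise FormatError("birth_order must be 1 or 2")

        dup = df.duplicated(subset=["family_id", "birth_order"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise DuplicateRecordError(
                f"duplicate (family_id, birth_order)=({df['family_id'].iloc[i]}, "
                f"{df['birth_order'].iloc[i]}) at row {i}"
            )

        for fam, sub in df.groupby("family_id", sort=False):
            codes = sub["zygosity"].unique()
            if len(codes) > 1:
                raise ConsistencyError(f"family {fam} has conflicting zygosity codes {list(codes)}")
            code = codes[0]
            n = len(sub)
            if code in SINGLETON_GROUPS and n != 1:
                raise ConsistencyError(f"singleton family {fam} has {n} records")
            if code in PAIR_GROUPS and n > 2:
                raise ConsistencyError(f"pair family {fam} has {n} records")
            req = GROUP_SEX.get(code)
            if req is not None:
                if not (sub["sex"] == req).all():
                    raise ConsistencyError(f"family {fam} ({code}) contains a non-{req} member")
            else:  # DZOS
                sexes = list(sub["sex"])
                if len(sexes) == 2 and sexes[0] == sexes[1]:
                    raise ConsistencyError(f"DZOS family {fam} has two same-sex members")

    # -- basic accessors ----------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def n_records(self) -> int:
        return len(self._df)

    @property
    def groups(self) -> dict[str, ZygosityGroup]:
        """family_id -> group."""
        sub = self._df.drop_duplicates("family_id")
        return {f: ZygosityGroup(z) for f, z in zip(sub["family_id"], sub["zygosity"])}

    @property
    def family_ids(self) -> list[str]:
        return list(self._df["family_id"].drop_duplicates())

    def group_counts(self) -> dict[str, int]:
        """Individuals per group code (only groups present)."""
        return self._df["zygosity"].value_counts().to_dict()

    def records(self) -> Iterator[TwinRecord]:
        for row in self._df.itertuples(index=False):
            yield TwinRecord(
                family_id=row.family_id,
                member_index=int(row.birth_order),
                sex=row.sex,
                age=float(row.age),
                measures={m: getattr(row, m) for m in self.measure_names},
            )

    def copy(self) -> "TwinDataset":
        return TwinDataset(self._df.copy(), self.measure_names, validate=False)

    def with_measure(self, name: str, values: np.ndarray) -> "TwinDataset":
        """Return a copy with measure ``name`` replaced/added (row-aligned)."""
        df = self._df.copy()
        df[name] = np.asarray(values, dtype=float)
        names = self.measure_names if name in self.measure_names else self.measure_names + [name]
        return TwinDataset(df, names, validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TwinDataset):
            return NotImplemented
        if self.measure_names != other.measure_names:
            return False
        a, b = self._df, other._df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in META_COLUMNS:
            if c == "age":
                continue
            if not (a[c] == b[c]).all():
                return False
        for c in ["age"] + self.measure_names:
            x, y = a[c].to_numpy(), b[c].to_numpy()
            if not (np.isclose(x, y, rtol=0, atol=0, equal_nan=True)).all():
                return False
        return True

    # -- likelihood input shape --------------------------------------------

    def pair_arrays(self, measure: str) -> dict[str, np.ndarray]:
        """Per-group arrays of family observation vectors for one measure.

        Pair groups map to ``(n_families, 2)`` arrays with NaN for missing
        members; singleton groups map to ``(n, 1)``.  Within DZOS pairs the
        male always occupies slot 1 (column 0) regardless of file order, so
        the male/female parameter mapping of the opposite-sex covariance is
        unambiguous.  Same-sex pairs are slotted by birth order.
        """
        if measure not in self.measure_names:
            raise KeyError(f"unknown measure {measure!r}")
        df = self._df
        out: dict[str, np.ndarray] = {}
        for code, sub in df.groupby("zygosity", sort=False):
            fams = sub["family_id"].drop_duplicates()
            if code in SINGLETON_GROUPS:
                out[code] = sub[measure].to_numpy(dtype=float).reshape(-1, 1)
                continue
            slot_col = sub["sex"].map({MALE: 1, FEMALE: 2}) if code == "DZOS" else sub["birth_order"]
            wide = (
                sub.assign(_slot=slot_col)
                .pivot(index="family_id", columns="_slot", values=measure)
                .reindex(index=fams, columns=[1, 2])
            )
            out[code] = wide.to_numpy(dtype=float)
        return out

    # -- I/O -----------------------------------------------------------------

    def write(self, path) -> None:
        """Write the long-format comma-separated file (empty cell = missing)."""
        self._df.to_csv(path, index=False)

    @classmethod
    def read(cls, path, measure_names: Iterable[str]) -> "TwinDataset":
        try:
            df = pd.read_csv(
                path,
                dtype={"family_id": str, "zygosity": str, "sex": str},
                float_precision="round_trip",
            )
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        return cls(df, measure_names)


def read_dataset(path, measure_names: Iterable[str]) -> TwinDataset:
    """Read and validate a long-format delimited phenotype file."""
    return TwinDataset.read(path, measure_names)


def write_dataset(dataset: TwinDataset, path) -> None:
    """Write ``dataset`` in the same dialect :func:`read_dataset` accepts."""
    dataset.write(path)


def pair_arrays(dataset: TwinDataset, measure: str) -> dict[str, np.ndarray]:
    """Module-level alias of :meth:`TwinDataset.pair_arrays`."""
    return dataset.pair_arrays(measure)
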