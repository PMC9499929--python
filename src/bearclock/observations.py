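"""In-memory observation table: one row per modeled hourly movement record."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import N_HOURS

OBS_COLUMNS = ["animal_id", "sex", "timestamp", "hour_index", "season",
               "rate_kmh", "y", "x1", "x2", "x3", "x4"]

_SEX_CODE = {"F": 1, "M": 2, 1: 1, 2: 2}


class ObservationTable:
    """Column-array view of the movement records a model is fitted to.

    Wraps the observation DataFrame (schema :data:`OBS_COLUMNS`) as integer /
    float numpy arrays: ``hour`` 1-24, ``season`` 1-4, ``sex`` 1 (F) / 2 (M),
    ``animal`` 0-based codes, ``y`` the sqrt-rate response, and ``x`` the
    distance covariates in km.  Mapping-style access (``obs["hour"]``) keeps
    it interchangeable with a plain dict in the model functions.
    """

    def __init__(self, hour, season, sex, animal, y, x, animal_ids=None, rate=None):
        self.hour = np.asarray(hour, dtype=int)
        self.season = np.asarray(season, dtype=int)
        self.sex = np.asarray(sex, dtype=int)
        self.animal = np.asarray(animal, dtype=int)
        self.y = np.asarray(y, dtype=float)
        self.x = {j: np.asarray(x[j], dtype=float) for j in x}
        self.animal_ids = list(animal_ids) if animal_ids is not None else sorted(set(self.animal))
        self.rate = np.asarray(rate, float) if rate is not None else self.y ** 2
        self._validate()

    def _validate(self):
        n = self.y.size
        for name in ("hour", "season", "sex", "animal"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} has wrong length")
        if n:
            if self.hour.min() < 1 or self.hour.max() > N_HOURS:
                raise ValueError("hour_index out of 1..24")
            if self.season.min() < 1 or self.season.max() > 4:
                raise ValueError("season out of 1..4")
            if not np.isin(self.sex, (1, 2)).all():
                raise ValueError("sex code must be 1 (F) or 2 (M)")
        for j, v in self.x.items():
            if v.size != n:
                raise ValueError(f"covariate x{j} has wrong length")
            if n and v.min() < -1e-12:
                raise ValueError(f"covariate x{j} has negative distances")

    def __len__(self) -> int:
        return self.y.size

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def __getitem__(self, key):
        return {"hour": self.hour, "season": self.season, "sex": self.sex,
                "animal": self.animal, "y": self.y, "x": self.x}[key]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, animal_ids=None) -> "ObservationTable":
        missing = [c for c in ("animal_id", "sex", "hour_index", "season", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"observation table is missing columns: {missing}")
        if animal_ids is None:
            animal_ids = sorted(df["animal_id"].unique())
        code = {a: i for i, a in enumerate(animal_ids)}
        x = {}
        for j in (1, 2, 3, 4):
            col = f"x{j}"
            x[j] = df[col].to_numpy(float) if col in df.columns else np.zeros(len(df))
        return cls(
            hour=df["hour_index"].to_numpy(int),
            season=df["season"].to_numpy(int),
            sex=df["sex"].map(_SEX_CODE).to_numpy(int),
            animal=df["animal_id"].map(code).to_numpy(int),
            y=df["y"].to_numpy(float),
            x=x,
            animal_ids=animal_ids,
            rate=df["rate_kmh"].to_numpy(float) if "rate_kmh" in df.columns else None,
        )

    @classmethod
    def empty(cls, n_animals: int = 1) -> "ObservationTable":
        """Zero-row table (prior-only fitting) with a declared animal count."""
        z = np.zeros(0)
        return cls(hour=z, season=z, sex=z, animal=z, y=z,
                   x={j: z for j in (1, 2, 3, 4)}, animal_ids=list(range(n_animals)))
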