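"""Run histories: every evaluated individual, per-generation populations.

Both inference engines record each evaluated candidate (an ``Individual``:
flat parameter vector, fitness breakdown, provenance id) and a snapshot of
the population membership at the end of every generation.  Histories are
the input to all post-hoc diagnostics (posterior extraction, ordination,
clustering, FVA sampling) and round-trip losslessly through CSV + a JSON
metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .particles import FitnessBreakdown


@dataclass
class Individual:
    particle_id: str
    generation: int
    values: np.ndarray
    fitness: FitnessBreakdown

    @property
    def overall(self) -> float:
        return self.fitness.overall


@dataclass
class RunHistory:
    param_names: list[str]
    records: list[Individual] = field(default_factory=list)
    populations: list[list[str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    # -- accessors ----------------------------------------------------------

    def _by_id(self) -> dict[str, Individual]:
        return {r.particle_id: r for r in self.records}

    def population(self, generation: int = -1) -> list[Individual]:
        idx = self._by_id()
        return [idx[pid] for pid in self.populations[generation]]

    @property
    def final_population(self) -> list[Individual]:
        return self.population(-1)

    @property
    def n_generations(self) -> int:
        return len(self.populations)

    def best(self) -> Individual:
        return max(self.records, key=lambda r: r.overall)

    def posterior(self, threshold: float) -> list[Individual]:
        """All evaluated individuals with overall R² above the threshold."""
        return [r for r in self.records if r.overall > threshold]

    def generation_summary(self) -> pd.DataFrame:
        """Median and 5th/95th percentile population fitness per generation."""
        rows = []
        idx = self._by_id()
        for g, pids in enumerate(self.populations):
            f = np.array([idx[p].overall for p in pids])
            rows.append({"generation": g, "best": f.max(),
                         "median": float(np.median(f)),
                         "p05": float(np.percentile(f, 5)),
                         "p95": float(np.percentile(f, 95)),
                         "min": f.min()})
        return pd.DataFrame(rows)

    # -- serialization ------------------------------------------------------

    def records_frame(self) -> pd.DataFrame:
        comp_keys: list[str] = []
        for r in self.records:
            for k in r.fitness.components:
                if k not in comp_keys:
                    comp_keys.append(k)
        rows = []
        for r in self.records:
            row: dict[str, object] = {"particle_id": r.particle_id,
                                      "generation": r.generation,
                                      "R2_overall": r.overall}
            for k in comp_keys:
                row[f"R2_{k}"] = r.fitness.components.get(k, np.nan)
            row.update(zip(self.param_names, r.values))
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rec = self.records_frame()
        rec.to_csv(d / "records.csv", index=False,
                   float_format="%.17g")
        pop_rows = [{"generation": g, "particle_id": pid}
                    for g, pids in enumerate(self.populations)
                    for pid in pids]
        pd.DataFrame(pop_rows).to_csv(d / "populations.csv", index=False)
        meta = dict(self.meta)
        meta["param_names"] = self.param_names
        meta["n_records"] = len(self.records)
        meta["n_population_rows"] = len(pop_rows)
        with open(d / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "RunHistory":
        d = Path(directory)
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
        rec = pd.read_csv(d / "records.csv", float_precision="round_trip")
        pops = pd.read_csv(d / "populations.csv")
        if len(rec) != meta["n_records"] or len(pops) != meta["n_population_rows"]:
            raise IOError(
                f"history in {d} is corrupt: row counts do not match metadata"
            )
        param_names = meta.pop("param_names")
        comp_cols = [c for c in rec.columns
                     if c.startswith("R2_") and c != "R2_overall"]
        records = []
        for row in rec.itertuples(index=False):
            dct = dict(zip(rec.columns, row))
            comps = {c[3:]: float(dct[c]) for c in comp_cols
                     if not pd.isna(dct[c])}
            fitness = FitnessBreakdown(components=comps,
                                       overall=float(dct["R2_overall"]))
            values = np.array([dct[c] for c in param_names], float)
            records.append(Individual(str(dct["particle_id"]),
                                      int(dct["generation"]), values, fitness))
        populations: list[list[str]] = []
        for g, grp in pops.groupby("generation", sort=True):
            populations.append([str(p) for p in grp["particle_id"]])
        meta.pop("n_records", None)
        meta.pop("n_population_rows", None)
        return cls(param_names=list(param_names), records=records,
                   populations=populations, meta=meta)
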