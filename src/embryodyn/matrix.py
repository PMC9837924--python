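"""Gene x (stage, replicate) matrices with declared units.

Columns follow the ``STAGE.REP`` naming convention (e.g. ``DPA8.r1``); the
stage order is carried explicitly because developmental stages are ordinal,
not lexicographic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

UNITS = ("counts", "TPM", "signal")


class StageMatrix:
    """Non-negative gene x (stage, replicate) matrix.

    Parameters
    ----------
    values : DataFrame indexed by gene id with ``STAGE.REP`` columns.
    stages : ordered stage labels; every stage must own >= 1 column.
    units : one of ``counts``, ``TPM``, ``signal``.
    """

    def __init__(self, values: pd.DataFrame, stages: Sequence[str],
                 units: str = "counts"):
        if units not in UNITS:
            raise ValueError(f"unknown units {units!r}")
        if (np.asarray(values.values, dtype=float) < 0).any():
            raise ValueError("negative values in StageMatrix")
        stages = list(stages)
        col_stage = {}
        for col in values.columns:
            stage, _, rep = str(col).rpartition(".")
            if not stage or not rep:
                raise ValueError(f"column {col!r} is not STAGE.REP formatted")
            if stage not in stages:
                raise ValueError(f"column {col!r} references unknown stage {stage!r}")
            col_stage[col] = stage
        for s in stages:
            if s not in col_stage.values():
                raise ValueError(f"stage {s!r} has no replicate column")
        self.df = values.astype(float)
        self.stages = stages
        self.units = units
        self._col_stage = col_stage

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    def replicates(self, stage: str) -> list[str]:
        return [c for c, s in self._col_stage.items() if s == stage]

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.df[self.replicates(stage)]

    def stage_means(self) -> pd.DataFrame:
        """Gene x stage matrix of replicate means, stages in declared order."""
        cols = {s: self.stage_values(s).mean(axis=1) for s in self.stages}
        return pd.DataFrame(cols, index=self.df.index)[self.stages]

    def zscored_stage_means(self, drop_constant: bool = True) -> pd.DataFrame:
        """Per-gene z-scored stage-mean profiles; constant genes dropped
        (or zero-filled when ``drop_constant`` is False)."""
        m = self.stage_means()
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=0)
        if drop_constant:
            m = m.loc[sd > 0]
            mu, sd = mu[sd > 0], sd[sd > 0]
            return m.sub(mu, axis=0).div(sd, axis=0)
        z = m.sub(mu, axis=0)
        nz = sd > 0
        z.loc[nz] = z.loc[nz].div(sd[nz], axis=0)
        return z

    def subset(self, gene_ids: Sequence[str]) -> "StageMatrix":
        return StageMatrix(self.df.loc[list(gene_ids)], self.stages, self.units)

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(f"# units={self.units} stages={','.join(self.stages)}\n")
            cols = list(self.df.columns)
            fh.write("gene\t" + "\t".join(cols) + "\n")
            for gid, row in self.df.iterrows():
                fh.write(gid + "\t" + "\t".join(format(v, ".6g") for v in row)
                         + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, stages: Sequence[str] | None = None,
                 units: str | None = None) -> "StageMatrix":
        meta_units, meta_stages = "counts", None
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            if "units=" in line:
                for tok in line[1:].split():
                    if tok.startswith("units="):
                        meta_units = tok.split("=", 1)[1]
                    elif tok.startswith("stages="):
                        meta_stages = tok.split("=", 1)[1].split(",")
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                         index_col=0)
        if stages is None:
            if meta_stages is not None:
                stages = meta_stages
            else:  # infer from column order, first occurrence wins
                seen = []
                for col in df.columns:
                    s = str(col).rpartition(".")[0]
                    if s not in seen:
                        seen.append(s)
                stages = seen
        return cls(df, stages, units or meta_units)
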