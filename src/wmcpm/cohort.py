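"""Cohort container shared across pipeline stages.

A cohort bundles per-participant behavioral scores, covariates, a motion
summary, and one canonical edge vector per participant (rows of ``edges``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Cohort:
    """Per-participant scores, covariates and connectome edge vectors.

    Attributes
    ----------
    ids : array of participant identifiers (strings).
    gf : behavioral score per participant.
    edges : (n_participants, n_edges) matrix of Fisher-z edge values in
        canonical upper-triangle order.
    mean_fd : mean framewise displacement (mm) per participant.
    age, sex : covariates (sex coded 0/1).
    n_nodes : node count the edge order refers to.
    session : free-form session tag (e.g. ``"time1"``).
    """

    ids: np.ndarray
    gf: np.ndarray
    edges: np.ndarray
    mean_fd: np.ndarray
    age: np.ndarray = field(default=None)
    sex: np.ndarray = field(default=None)
    n_nodes: int = 0
    session: str = "time1"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.gf = np.asarray(self.gf, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        n = len(self.ids)
        if self.edges.shape[0] != n or len(self.gf) != n:
            raise ValueError("ids, gf and edges must agree on participant count")
        self.mean_fd = (
            np.zeros(n) if self.mean_fd is None else np.asarray(self.mean_fd, dtype=float)
        )
        if self.age is None:
            self.age = np.full(n, np.nan)
        if self.sex is None:
            self.sex = np.full(n, np.nan)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)

    @property
    def n_participants(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def participant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "gf": self.gf,
                "age": self.age,
                "sex": self.sex,
                "mean_fd": self.mean_fd,
                "session": self.session,
            }
        )

    def write(self, directory: str | Path) -> None:
        """Write participant CSV plus a participants-by-edges matrix (TSV)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participant_table().to_csv(directory / "participants.csv", index=False)
        np.savetxt(directory / "edges.tsv", self.edges, delimiter="\t")

    @classmethod
    def read(cls, directory: str | Path, n_nodes: int = 0) -> "Cohort":
        directory = Path(directory)
        table = pd.read_csv(directory / "participants.csv")
        edges = np.loadtxt(directory / "edges.tsv", delimiter="\t", ndmin=2)
        session = str(table["session"].iloc[0]) if "session" in table else "time1"
        return cls(
            ids=table["id"].to_numpy(),
            gf=table["gf"].to_numpy(),
            edges=edges,
            mean_fd=table["mean_fd"].to_numpy() if "mean_fd" in table else None,
            age=table["age"].to_numpy() if "age" in table else None,
            sex=table["sex"].to_numpy() if "sex" in table else None,
            n_nodes=n_nodes,
            session=session,
        )
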