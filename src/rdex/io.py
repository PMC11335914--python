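"""Trial-table I/O, preprocessing and run configuration.

The on-disk trial format is comma-delimited UTF-8 text with a header, one
row per trial and RT/SSD in seconds; missing values (SSD on go trials, RT
and response on omissions) are empty fields. The schema is validated on
read with row-level error messages, and write -> read round-trips are
lossless.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRIAL_COLUMNS",
    "SchemaError",
    "read_trials",
    "write_trials",
    "preprocess",
    "write_samples",
    "read_samples",
    "RunConfig",
]

TRIAL_COLUMNS = [
    "subject",
    "session",
    "block",
    "trial",
    "block_type",
    "bias",
    "difficulty",
    "stimulus",
    "trial_type",
    "ssd",
    "response",
    "rt",
]

_LEVELS = {
    "block_type": {"block", "trial"},
    "bias": {"blue", "orange"},
    "difficulty": {"easy", "hard"},
    "stimulus": {"blue", "orange"},
    "trial_type": {"go", "stop"},
    "response": {"blue", "orange", "none"},
}

_MAX_ERRORS = 10


class SchemaError(ValueError):
    """A trial table violates the schema; the message lists offending rows."""


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    errors: list[str] = []
    for col, levels in _LEVELS.items():
        bad = ~table[col].isin(levels)
        for i in table.index[bad][:_MAX_ERRORS]:
            errors.append(f"row {i}: invalid {col} {table.at[i, col]!r}")
    ssd = pd.to_numeric(table["ssd"], errors="coerce")
    rt = pd.to_numeric(table["rt"], errors="coerce")
    is_stop = table["trial_type"] == "stop"
    responded = table["response"].isin({"blue", "orange"})
    checks = [
        (is_stop & ssd.isna(), "stop trial without ssd"),
        (~is_stop & ssd.notna(), "go trial with non-empty ssd"),
        (responded & (rt.isna() | (rt <= 0)), "responded trial requires rt > 0"),
        (~responded & rt.notna(), "trial without response carries an rt"),
    ]
    for bad, msg in checks:
        for i in table.index[bad][:_MAX_ERRORS]:
            errors.append(f"row {i}: {msg}")
    if errors:
        raise SchemaError("invalid trial table:\n" + "\n".join(errors[:_MAX_ERRORS]))


def read_trials(path, column_aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and schema-validate a trial table from CSV.

    ``column_aliases`` maps foreign column names to the canonical schema
    (e.g. ``{"RT": "rt", "SSD": "ssd"}``) so externally produced files can
    be imported without rewriting them.
    """
    table = pd.read_csv(
        path,
        dtype={"subject": str, "response": str},
        keep_default_na=True,
    )
    if column_aliases:
        table = table.rename(columns=column_aliases)
    if "response" in table.columns:
        table["response"] = table["response"].astype(str)
        table.loc[table["response"].isin(["nan", ""]), "response"] = "none"
        table["response"] = table["response"].fillna("none")
    _validate(table)
    table["ssd"] = pd.to_numeric(table["ssd"], errors="coerce")
    table["rt"] = pd.to_numeric(table["rt"], errors="coerce")
    return table


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (empty fields for missing values)."""
    _validate(table)
    table.to_csv(path, index=False)


def preprocess(table: pd.DataFrame, rt_floor: float = 0.2):
    """Remove implausibly fast responses (RT below ``rt_floor`` seconds,
    0.2 by default). Returns the filtered table and a removal report."""
    rt = pd.to_numeric(table["rt"], errors="coerce")
    fast = rt.notna() & (rt < rt_floor)
    kept = table.loc[~fast].reset_index(drop=True)
    n = len(table)
    report = {
        "rt_floor": rt_floor,
        "n_input": n,
        "n_removed": int(fast.sum()),
        "fraction_removed": float(fast.sum() / n) if n else 0.0,
    }
    return kept, report


def write_samples(samples, path) -> None:
    """Serialize retained posterior draws as a long-format CSV (chain,
    iteration, one column per parameter)."""
    samples.to_frame().to_csv(path, index=False)


def read_samples(path):
    """Read posterior draws written by :func:`write_samples` back into a
    :class:`~rdex.inference.PosteriorSamples`."""
    from .inference import PosteriorSamples

    frame = pd.read_csv(path)
    labels = [c for c in frame.columns if c not in ("chain", "iteration")]
    chains = np.sort(frame["chain"].unique())
    iters = np.sort(frame["iteration"].unique())
    draws = np.empty((chains.size, iters.size, len(labels)))
    for k, c in enumerate(chains):
        sub = frame[frame["chain"] == c].sort_values("iteration")
        draws[k] = sub[labels].to_numpy()
    return PosteriorSamples(draws, labels, thin=1, burn_iterations=0, converged=True)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Single source of truth for every run setting.

    Defaults reproduce the reference settings: thin 5, 5% migration, 250
    retained draws per chain, R-hat threshold 1.1, chains = 3x the free
    parameter count (``chains: null``), 2 s deadline, staircase start 0.2 s
    with 0.05 s steps, 15 stop trials per 60-trial block (25% stop trials)
    and a 0.2 s RT floor in preprocessing.
    """

    map_assignment: dict | None = None  # None -> selective-influence default
    priors: dict | None = None  # None -> default prior table
    column_aliases: dict | None = None  # foreign -> canonical column names
    chains: int | None = None
    thin: int = 5
    migration_prob: float = 0.05
    n_keep: int = 250
    rhat_threshold: float = 1.1
    max_iter: int = 5000
    burn_min: int = 200
    deadline: float = 2.0
    staircase_start: float = 0.2
    staircase_step: float = 0.05
    n_sessions: int = 2
    blocks_per_session: int = 8
    trials_per_block: int = 60
    stop_per_block: int = 15
    stop_lower: float = 0.05
    rt_floor: float = 0.2
    gl_nodes: int = 16
    seed: int = 0

    @property
    def stop_proportion(self) -> float:
        return self.stop_per_block / self.trials_per_block

    def build_map(self):
        from .design import build_map

        assignment = self.map_assignment
        if assignment is not None:
            assignment = {k: tuple(v) for k, v in assignment.items()}
        return build_map(assignment)

    def build_prior(self, pmap):
        from .inference import PriorSpec

        table = None
        if self.priors is not None:
            table = {
                k: (v[0], v[1], v[2] if v[2] is not None else -math.inf,
                    v[3] if v[3] is not None else math.inf)
                for k, v in self.priors.items()
            }
        return PriorSpec.from_map(pmap, table)

    def sampler_kwargs(self) -> dict:
        return {
            "n_chains": self.chains,
            "thin": self.thin,
            "migration_prob": self.migration_prob,
            "n_keep": self.n_keep,
            "rhat_threshold": self.rhat_threshold,
            "max_iter": self.max_iter,
            "burn_min": self.burn_min,
            "gl_nodes": self.gl_nodes,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
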