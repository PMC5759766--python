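"""Core containers and file I/O.

The canonical on-disk dialect is TSV: UTF-8, no quoting, ``.`` decimal
separator.  A count matrix is written with gene identifiers in the first
column and a header row of sample identifiers; a design table has one row
per sample with columns ``sample``, ``genotype`` and ``role``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DesignError, ParameterError, ParseError

ROLES = ("parent1", "parent2", "hybrid")


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

class CountMatrix:
    """A gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by unique gene identifiers, with unique sample
        identifiers as columns.  Entries must be non-negative integers
        (integral floats are accepted and cast).
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ParameterError("counts: need at least one gene and two samples")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ParameterError(f"counts: duplicate gene id {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ParameterError(f"counts: duplicate sample id {dup!r}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParameterError("counts: non-numeric entries present")
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            g, s = map(int, np.argwhere(bad)[0])
            raise ParameterError(
                f"counts: invalid entry {values[g, s]!r} at gene "
                f"{counts.index[g]!r}, sample {counts.columns[s]!r} "
                "(must be a non-negative integer)"
            )
        df = counts.astype(np.int64)
        df.index = df.index.astype(str)
        df.index.name = "gene_id"
        df.columns = df.columns.astype(str)
        self.df = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


# ---------------------------------------------------------------------------
# TriadDesign
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TriadDesign:
    """Sample-to-genotype assignment plus the triad roles of the genotypes.

    ``genotype_of`` maps every sample to its genotype; ``role_of`` maps each
    of exactly three genotypes to one of the roles ``parent1``, ``parent2``
    and ``hybrid``.  Every genotype must carry at least two replicates.
    """

    genotype_of: Mapping[str, str]
    role_of: Mapping[str, str]

    def __post_init__(self):
        if not self.genotype_of:
            raise DesignError("design: no samples")
        roles = list(self.role_of.values())
        if sorted(roles) != sorted(ROLES):
            raise DesignError(
                f"design: roles must be exactly {set(ROLES)}, got {roles}"
            )
        known = set(self.role_of)
        for sample, geno in self.genotype_of.items():
            if geno not in known:
                raise DesignError(
                    f"design: sample {sample!r} has genotype {geno!r} "
                    "which carries no triad role"
                )
        for geno in known:
            n = sum(1 for g in self.genotype_of.values() if g == geno)
            if n < 2:
                raise DesignError(
                    f"design: genotype {geno!r} has {n} replicate(s); need >= 2"
                )

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(self.role_of)

    def samples_of(self, genotype: str) -> list[str]:
        if genotype not in self.role_of:
            raise DesignError(f"design: unknown genotype {genotype!r}")
        return [s for s, g in self.genotype_of.items() if g == genotype]

    def genotype_for_role(self, role: str) -> str:
        for geno, r in self.role_of.items():
            if r == role:
                return geno
        raise DesignError(f"design: no genotype with role {role!r}")

    def relabel_parents(self) -> "TriadDesign":
        """Return a design with the parent1/parent2 role labels swapped."""
        swap = {"parent1": "parent2", "parent2": "parent1", "hybrid": "hybrid"}
        return TriadDesign(dict(self.genotype_of),
                           {g: swap[r] for g, r in self.role_of.items()})


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header of sample ids).

    Raises :class:`ParseError` locating the offending line/cell on malformed
    input, including negative or non-integer entries and duplicate ids.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0,
                         dtype_backend="numpy_nullable")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV count matrix: {exc}") from exc
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().to_numpy().any():
        mask = df.isna().to_numpy()
        g, s = map(int, np.argwhere(mask)[0])
        raise ParseError(
            f"{path}: non-numeric entry at line {g + 2}, gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    try:
        return CountMatrix(df.astype(float))
    except ParameterError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_count_matrix(counts: CountMatrix, path: str | Path) -> None:
    counts.df.to_csv(path, sep="\t")


def read_design(path: str | Path) -> TriadDesign:
    """Read a design TSV with columns sample, genotype, role."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "genotype", "role"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: design needs columns {sorted(required)}")
    genotype_of = dict(zip(df["sample"], df["genotype"]))
    if len(genotype_of) != len(df):
        raise ParseError(f"{path}: duplicate sample ids in design")
    role_of: dict[str, str] = {}
    for _, row in df.iterrows():
        prev = role_of.setdefault(row["genotype"], row["role"])
        if prev != row["role"]:
            raise ParseError(
                f"{path}: genotype {row['genotype']!r} assigned roles "
                f"{prev!r} and {row['role']!r}"
            )
    try:
        return TriadDesign(genotype_of, role_of)
    except DesignError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_design(design: TriadDesign, path: str | Path) -> None:
    rows = [{"sample": s, "genotype": g, "role": design.role_of[g]}
            for s, g in design.genotype_of.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration and run manifest
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Configuration of an end-to-end run.

    Thresholds are significance levels in (0, 1); ``pseudocount`` is the
    offset added to normalized means when reporting log2 fold changes;
    ``shrink_weight`` is the weight pulling per-gene dispersions toward the
    trimmed-mean dispersion.
    """

    counts: str = ""
    design: str = ""
    annotation: str | None = None
    qpcr: str | None = None
    out_dir: str = "triadexpr_out"
    alpha_de: float = 0.05
    alpha_enrich: float = 0.05
    alpha_qpcr: float = 0.05
    pseudocount: float = 0.5
    shrink_weight: float = 0.5
    midparent_test: bool = True
    min_term_size: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("alpha_de", "alpha_enrich", "alpha_qpcr"):
            v = getattr(self, name)
            if not (0 < v < 1) and v != 1.0:
                raise ParameterError(f"{name}: must be in (0, 1]")
        if self.pseudocount < 0:
            raise ParameterError("pseudocount: must be >= 0")
        if not (0 <= self.shrink_weight <= 1):
            raise ParameterError("shrink_weight: must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig, out_path: str | Path,
                   inputs: Mapping[str, str | Path] | None = None) -> dict:
    """Write a machine-readable run manifest (versions, seed, config echo)."""
    import scipy

    from . import __version__

    manifest = {
        "triadexpr": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in (inputs or {}).items()},
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
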