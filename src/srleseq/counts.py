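"""Element-by-sample count tables for fractionation screens.

The central container of the pipeline: one row per distinct insert (or gene),
one column per sequenced sample, with sample metadata (fraction, replicate,
optional condition) and per-sample invalid-read tallies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"
FRACTIONS = (NUCLEAR, CYTOPLASMIC)


@dataclass(frozen=True)
class FractionSample:
    """One sequenced sample: a fraction, a replicate id, optional condition/depth."""

    fraction: str
    replicate: int
    depth: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if self.replicate < 1:
            raise ValueError("replicate ids start at 1")

    @property
    def name(self) -> str:
        if self.condition is not None:
            return f"{self.condition}_{self.fraction}_{self.replicate}"
        return f"{self.fraction}_{self.replicate}"

    @classmethod
    def from_name(cls, name: str, depth: int | None = None) -> "FractionSample":
        parts = name.split("_")
        if len(parts) == 2:
            fraction, rep = parts
            condition = None
        elif len(parts) == 3:
            condition, fraction, rep = parts
        else:
            raise ValueError(f"cannot parse sample name {name!r}")
        return cls(fraction=fraction, replicate=int(rep), depth=depth, condition=condition)


@dataclass
class CountTable:
    """Raw counts of elements across fraction samples.

    ``counts`` is an integer matrix of shape (len(elements), len(samples));
    column order matches ``samples``.  ``invalid_reads`` counts reads per
    sample that failed anchor matching during extraction.
    """

    elements: list[str]
    samples: list[FractionSample]
    counts: np.ndarray
    invalid_reads: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.elements), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.elements)} elements x {len(self.samples)} samples"
            )
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("element sequences must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.invalid_reads is None:
            self.invalid_reads = np.zeros(len(self.samples), dtype=np.int64)
        else:
            self.invalid_reads = np.asarray(self.invalid_reads, dtype=np.int64)
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names (replicate ids must be unique per fraction)")

    # -- convenience ---------------------------------------------------

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def columns(self, fraction: str, condition: str | None = None) -> np.ndarray:
        """Column indices of the given fraction (and condition, if set)."""
        idx = [
            j
            for j, s in enumerate(self.samples)
            if s.fraction == fraction and (condition is None or s.condition == condition)
        ]
        if not idx:
            raise ValueError(f"no samples for fraction={fraction!r} condition={condition!r}")
        return np.asarray(idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.elements, name="element"),
                            columns=self.sample_names)

    # -- TSV round trip ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the table: TSV body, then invalid-read tallies as # comments."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("element\t" + "\t".join(self.sample_names) + "\n")
            body = io.StringIO()
            self.to_frame().to_csv(body, sep="\t", header=False)
            fh.write(body.getvalue())
            tallies = " ".join(
                f"{n}={v}" for n, v in zip(self.sample_names, self.invalid_reads)
            )
            fh.write(f"# invalid_reads: {tallies}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        path = Path(path)
        invalid: dict[str, int] = {}
        rows: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if line.startswith("# invalid_reads:"):
                        for item in line.split(":", 1)[1].split():
                            k, v = item.split("=")
                            invalid[k] = int(v)
                    continue
                rows.append(line)
        df = pd.read_csv(io.StringIO("".join(rows)), sep="\t", index_col="element")
        samples = [FractionSample.from_name(c) for c in df.columns]
        inv = np.array([invalid.get(c, 0) for c in df.columns], dtype=np.int64)
        return cls(
            elements=[str(e) for e in df.index],
            samples=samples,
            counts=df.to_numpy(dtype=np.int64),
            invalid_reads=inv,
        )
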