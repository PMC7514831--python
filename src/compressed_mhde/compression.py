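"""Random-projection compression of raw data blocks.

Raw observations arrive as B blocks of J values each.  Every block
``x_l`` is multiplied by a fresh S x J sensing matrix ``R_l`` of i.i.d.
random weights, producing S compressed values per block.  Only the
triplets ``(y_tilde, r_sum, omega)`` are stored::

    y_tilde_il = sum_j R_ijl * x_jl        (projected value)
    r_sum_il   = sum_j R_ijl               (row sum of weights)
    omega_il   = sqrt(sum_j R_ijl**2)      (row Euclidean norm)

These three numbers per (channel, block) pair are sufficient for the
centered residual ``U = (y_tilde - mu * r_sum) / omega`` used by the
estimator; the sensing matrices themselves are never persisted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "gamma", "bernoulli", "degenerate")

CSV_COLUMNS = ["block", "channel", "y_tilde", "r_sum", "omega"]


class ConfigurationError(ValueError):
    """Invalid sensing specification or experiment configuration."""


class DegenerateRowError(ValueError):
    """A sensing-matrix row has zero Euclidean norm (omega = 0)."""


@dataclass(frozen=True)
class SensingSpec:
    """Distribution family and moments of the sensing weights.

    Parameters
    ----------
    family
        One of ``gaussian``, ``gamma``, ``bernoulli``, ``degenerate``.
    S
        Number of compressed channels (rows) per block.
    J
        Number of raw values per block.
    variance
        Variance ``gamma0**2`` of a single sensing weight.  For the
        Bernoulli family this is implied by ``p`` and must not be given.
    p
        Success probability, Bernoulli family only.

    Gaussian and gamma weights have mean 1 (the standing assumption of
    the compression scheme); Bernoulli weights have mean ``p``.
    """

    family: str
    S: int
    J: int
    variance: float = 0.0
    p: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unsupported sensing family {self.family!r}")
        if self.S < 1 or self.J < 1:
            raise ConfigurationError("S and J must be positive integers")
        if self.family == "bernoulli":
            if self.p is None or not (0.0 < self.p <= 1.0):
                raise ConfigurationError("bernoulli sensing requires p in (0, 1]")
            implied = self.p * (1.0 - self.p)
            if self.variance not in (0.0, implied):
                raise ConfigurationError(
                    "bernoulli variance is implied by p; do not set it"
                )
            object.__setattr__(self, "variance", implied)
        else:
            if self.p is not None:
                raise ConfigurationError("p is only meaningful for bernoulli sensing")
            if self.variance < 0.0:
                raise ConfigurationError("variance must be nonnegative")
            if self.family == "degenerate" and self.variance != 0.0:
                raise ConfigurationError("degenerate sensing has zero variance")
            if self.family == "gamma" and self.variance == 0.0:
                raise ConfigurationError("gamma sensing requires positive variance")

    @property
    def mean(self) -> float:
        """Expected value of one sensing weight."""
        return self.p if self.family == "bernoulli" else 1.0

    @property
    def gamma0(self) -> float:
        """Standard deviation of one sensing weight."""
        return float(np.sqrt(self.variance))

    @classmethod
    def gaussian(cls, gamma0: float, S: int = 1, J: int = 10_000) -> "SensingSpec":
        if gamma0 == 0.0:
            return cls("degenerate", S=S, J=J)
        return cls("gaussian", S=S, J=J, variance=gamma0**2)

    @classmethod
    def gamma(cls, variance: float, S: int = 1, J: int = 10_000) -> "SensingSpec":
        if variance == 0.0:
            return cls("degenerate", S=S, J=J)
        return cls("gamma", S=S, J=J, variance=variance)

    @classmethod
    def bernoulli(cls, p: float, S: int = 1, J: int = 10) -> "SensingSpec":
        return cls("bernoulli", S=S, J=J, p=p)

    @classmethod
    def degenerate(cls, S: int = 1, J: int = 10_000) -> "SensingSpec":
        return cls("degenerate", S=S, J=J)

    def to_dict(self) -> dict:
        d = {"family": self.family, "S": self.S, "J": self.J, "variance": self.variance}
        if self.p is not None:
            d["p"] = self.p
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SensingSpec":
        return cls(
            family=d["family"],
            S=int(d["S"]),
            J=int(d["J"]),
            variance=float(d.get("variance", 0.0)) if d["family"] != "bernoulli" else 0.0,
            p=float(d["p"]) if d.get("p") is not None else None,
        )


@dataclass(frozen=True)
class CompressedRecord:
    """One stored triplet for block ``block`` (1-based) and channel ``channel`` (1..S).

    ``omega = 0`` marks an empty projection row (possible only under
    Bernoulli sensing, when a row of weights comes out all zero); such
    records are stored but carry no residual information.
    """

    block: int
    channel: int
    y_tilde: float
    r_sum: float
    omega: float

    def __post_init__(self) -> None:
        if self.omega < 0.0:
            raise DegenerateRowError(
                f"omega must be nonnegative (block {self.block}, channel {self.channel})"
            )


@dataclass
class CompressedDataset:
    """All stored triplets for S channels and B blocks.

    Arrays are shaped ``(S, B)`` and indexed ``[channel-1, block-1]``.
    """

    y_tilde: np.ndarray
    r_sum: np.ndarray
    omega: np.ndarray
    spec: SensingSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.y_tilde = np.asarray(self.y_tilde, dtype=float)
        self.r_sum = np.asarray(self.r_sum, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        shapes = {self.y_tilde.shape, self.r_sum.shape, self.omega.shape}
        if len(shapes) != 1 or self.y_tilde.ndim != 2:
            raise ValueError("y_tilde, r_sum and omega must share a 2-d (S, B) shape")
        if self.y_tilde.shape[0] != self.spec.S:
            raise ValueError("first axis must match spec.S")
        if self.B:
            # empty rows (omega = 0) can only arise under Bernoulli sensing
            floor = 0.0 if self.spec.family == "bernoulli" else np.finfo(float).tiny
            if np.any(self.omega < floor):
                raise DegenerateRowError("all omega values must be positive")

    @property
    def S(self) -> int:
        return self.y_tilde.shape[0]

    @property
    def B(self) -> int:
        return self.y_tilde.shape[1]

    def records(self) -> Iterator[CompressedRecord]:
        """Records in (block, channel) lexicographic storage order."""
        for l in range(self.B):
            for i in range(self.S):
                yield CompressedRecord(
                    block=l + 1,
                    channel=i + 1,
                    y_tilde=float(self.y_tilde[i, l]),
                    r_sum=float(self.r_sum[i, l]),
                    omega=float(self.omega[i, l]),
                )

    def channel(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays ``(y_tilde, r_sum, omega)`` of channel ``i`` (1-based), length B."""
        if not 1 <= i <= self.S:
            raise IndexError(f"channel {i} not in 1..{self.S}")
        return self.y_tilde[i - 1], self.r_sum[i - 1], self.omega[i - 1]

    def replace_y_tilde(self, y_tilde: np.ndarray) -> "CompressedDataset":
        return CompressedDataset(
            y_tilde=np.asarray(y_tilde, float),
            r_sum=self.r_sum.copy(),
            omega=self.omega.copy(),
            spec=self.spec,
        )

    def to_frame(self) -> pd.DataFrame:
        S, B = self.S, self.B
        block = np.repeat(np.arange(1, B + 1), S)
        channel = np.tile(np.arange(1, S + 1), B)
        return pd.DataFrame(
            {
                "block": block,
                "channel": channel,
                "y_tilde": self.y_tilde.T.ravel(),
                "r_sum": self.r_sum.T.ravel(),
                "omega": self.omega.T.ravel(),
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompressedDataset):
            return NotImplemented
        return (
            self.spec == other.spec
            and self.y_tilde.shape == other.y_tilde.shape
            and np.array_equal(self.y_tilde, other.y_tilde)
            and np.array_equal(self.r_sum, other.r_sum)
            and np.array_equal(self.omega, other.omega)
        )


def draw_sensing_matrix(
    spec: SensingSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw one S x J sensing matrix of i.i.d. weights from ``spec``."""
    S, J = spec.S, spec.J
    if spec.family == "degenerate":
        return np.ones((S, J))
    if spec.family == "gaussian":
        return rng.normal(1.0, spec.gamma0, size=(S, J))
    if spec.family == "gamma":
        # mean = shape*scale = 1, variance = shape*scale**2 = v
        v = spec.variance
        return rng.gamma(shape=1.0 / v, scale=v, size=(S, J))
    if spec.family == "bernoulli":
        # rows may come out all zero (probability (1-p)^J); they are kept,
        # stored as (0, 0, 0) triplets, and skipped by the residual transform
        return rng.binomial(1, spec.p, size=(S, J)).astype(float)
    raise ConfigurationError(f"unsupported sensing family {spec.family!r}")


def compress_block(
    x: np.ndarray, R: np.ndarray, allow_empty_rows: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compress one raw block ``x`` (length J) with sensing matrix ``R`` (S x J).

    Returns the per-channel arrays ``(y_tilde, r_sum, omega)`` of length S.
    Zero-norm rows raise unless ``allow_empty_rows`` (used for Bernoulli
    sensing, where an all-zero row is a legitimate draw).
    """
    x = np.asarray(x, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if x.ndim != 1 or R.shape[1] != x.shape[0]:
        raise ValueError(
            f"block length {x.shape} does not match sensing matrix {R.shape}"
        )
    y_tilde = R @ x
    r_sum = R.sum(axis=1)
    omega = np.sqrt((R**2).sum(axis=1))
    if np.any(omega <= 0.0) and not allow_empty_rows:
        raise DegenerateRowError("sensing row with zero norm (omega = 0)")
    return y_tilde, r_sum, omega


def block_seed_sequences(
    seed: int | np.random.SeedSequence, B: int
) -> list[np.random.SeedSequence]:
    """Independent per-block child streams of one root seed.

    Block ``l`` (0-based) always receives the same child stream, so any
    single block can be re-compressed in isolation.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return root.spawn(B)


def compress_stream(
    blocks: np.ndarray | Sequence[np.ndarray],
    spec: SensingSpec,
    seed: int | np.random.SeedSequence,
) -> CompressedDataset:
    """Compress B raw blocks with one fresh i.i.d. sensing matrix per block.

    ``blocks`` is a (B, J) array or a sequence of length-J arrays.  The
    per-block sensing matrices are drawn from per-block child streams of
    ``seed`` (see :func:`block_seed_sequences`).
    """
    if isinstance(blocks, np.ndarray):
        if blocks.size and blocks.ndim != 2:
            raise ValueError("blocks array must be 2-d (B, J)")
        block_list = list(blocks)
    else:
        block_list = [np.asarray(b, dtype=float) for b in blocks]
    B = len(block_list)
    if any(b.shape != (spec.J,) for b in block_list):
        raise ValueError(f"every block must have length J={spec.J}")

    y = np.empty((spec.S, B))
    rs = np.empty((spec.S, B))
    om = np.empty((spec.S, B))
    allow_empty = spec.family == "bernoulli"
    for l, child in enumerate(block_seed_sequences(seed, B)):
        rng = np.random.default_rng(child)
        R = draw_sensing_matrix(spec, rng)
        y[:, l], rs[:, l], om[:, l] = compress_block(
            block_list[l], R, allow_empty_rows=allow_empty
        )
    n_empty = int(np.count_nonzero(om == 0.0))
    if n_empty:
        logger.info("%d empty (all-zero) sensing row(s) among %d records", n_empty, y.size)
    return CompressedDataset(y_tilde=y, r_sum=rs, omega=om, spec=spec)


def write_dataset(path, dataset: CompressedDataset) -> None:
    """Write the stored triplets to CSV at full precision.

    The sensing specification is kept in comment lines (``# key=value``)
    ahead of the header so a dataset file is self-describing.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in dataset.spec.to_dict().items():
            fh.write(f"# {key}={val}\n")
        df = dataset.to_frame()
        df.to_csv(fh, index=False, float_format="%.17g")


def read_dataset(path) -> CompressedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = df[CSV_COLUMNS[2:]].isna().any(axis=1)
    if bad.any():
        # +2 for the header line, +len(meta) for comment lines, 1-based
        lineno = int(bad.idxmax()) + 2 + len(meta)
        raise ValueError(f"{path}: malformed row at line {lineno}")
    if "family" not in meta:
        raise ValueError(f"{path}: missing sensing specification header")
    spec = SensingSpec.from_dict(
        {
            "family": meta["family"],
            "S": int(meta["S"]),
            "J": int(meta["J"]),
            "variance": float(meta.get("variance", 0.0)),
            "p": float(meta["p"]) if "p" in meta else None,
        }
    )
    S = spec.S
    B = len(df) // S
    if len(df) != S * B:
        raise ValueError(f"{path}: record count {len(df)} not divisible by S={S}")
    df = df.sort_values(["block", "channel"], kind="stable")
    expect_block = np.repeat(np.arange(1, B + 1), S)
    expect_chan = np.tile(np.arange(1, S + 1), B)
    if not (
        np.array_equal(df["block"].to_numpy(), expect_block)
        and np.array_equal(df["channel"].to_numpy(), expect_chan)
    ):
        raise ValueError(f"{path}: (block, channel) indices are not dense")
    y = df["y_tilde"].to_numpy().reshape(B, S).T
    rs = df["r_sum"].to_numpy().reshape(B, S).T
    om = df["omega"].to_numpy().reshape(B, S).T
    return CompressedDataset(y_tilde=y, r_sum=rs, omega=om, spec=spec)
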