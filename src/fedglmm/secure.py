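"""Secure-aggregation primitives for the federated protocol.

Implements the additive plumbing the protocol simulation is built on:

* **Partitioned noise** — per-site Gaussian noise supported only on that
  site's rows; summed over sites it forms a dense mask no single party
  (including the server) can remove.
* **OTP-like masking** (``MaskBackend``) — symmetric protection by adding a
  seeded large-variance noise matrix, removed by the key holder after
  aggregation.  Additively homomorphic by construction.
* **Mock HE** (``MockHEBackend``) — a plaintext stand-in with the same
  additive-backend contract (encrypt = copy + session tag), used to exercise
  protocol flow without a lattice library; a real HE implementation can be
  registered under its own name.
* **EADP** — encrypt-aggregate-decrypt-partition: sites add partitioned
  noise, encrypt, round-robin sum; the server decrypts the aggregate (still
  carrying the summed partitioned noise), partitions it by rows and returns
  each site its own slice, from which the site removes its own noise.
* **Rotation masking** — sites share a random invertible p x p matrix Q and
  send Omega_j Q and Q^{-1} Xi^{-1} Omega_j' so the server can assemble
  Omega Xi^{-1} Omega' (hence P) without seeing Omega itself.
* **Quantization** — float32 round-trip of transfer matrices.

Every inter-party transfer is recorded in a :class:`Transcript` (JSON-lines
serializable) so tests can audit exactly what the server received.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_MASK_SCALE = 1e6


# ---------------------------------------------------------------------------
# transcript
# ---------------------------------------------------------------------------


@dataclass
class Message:
    sender: str
    receiver: str
    kind: str
    shape: tuple
    protected: bool
    stage: str = ""

    def to_dict(self) -> dict:
        return {
            "sender": self.sender,
            "receiver": self.receiver,
            "kind": self.kind,
            "shape": list(self.shape),
            "protected": self.protected,
            "stage": self.stage,
        }


class Transcript:
    """Ordered log of every inter-party matrix transfer."""

    def __init__(self) -> None:
        self.messages: list[Message] = []

    def log(
        self,
        sender: str,
        receiver: str,
        kind: str,
        shape: tuple,
        protected: bool,
        stage: str = "",
    ) -> None:
        self.messages.append(Message(sender, receiver, kind, shape, protected, stage))

    def received_by(self, party: str) -> list[Message]:
        return [m for m in self.messages if m.receiver == party]

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for m in self.messages:
                fh.write(json.dumps(m.to_dict()) + "\n")

    def __len__(self) -> int:
        return len(self.messages)


# ---------------------------------------------------------------------------
# partition bookkeeping and mask material
# ---------------------------------------------------------------------------


@dataclass
class PartitionPlan:
    """Global row partition of n samples into J contiguous site blocks."""

    site_sizes: list[int]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.site_sizes):
            raise ValueError("site sizes must be nonnegative")

    @property
    def total_n(self) -> int:
        return int(sum(self.site_sizes))

    @property
    def J(self) -> int:
        return len(self.site_sizes)

    @property
    def row_ranges(self) -> list[tuple[int, int]]:
        edges = np.concatenate([[0], np.cumsum(self.site_sizes)]).astype(int)
        return [(int(edges[j]), int(edges[j + 1])) for j in range(self.J)]

    def rows(self, j: int, M: np.ndarray) -> np.ndarray:
        lo, hi = self.row_ranges[j]
        return M[lo:hi]


def make_partitioned_noise(
    site_seed: int, shape: tuple, row_range: tuple[int, int], scale: float
) -> np.ndarray:
    """Gaussian noise (sd = scale) on the site's rows, exact zeros elsewhere.

    Bit-reproducible from ``site_seed``; an empty row range yields the zero
    matrix.
    """
    lo, hi = row_range
    if not (0 <= lo <= hi <= shape[0]):
        raise ValueError(f"row range {row_range} outside shape {shape}")
    out = np.zeros(shape)
    if hi > lo:
        rng = np.random.default_rng(site_seed)
        out[lo:hi] = rng.normal(0.0, scale, size=(hi - lo,) + tuple(shape[1:]))
    return out


@dataclass
class MaskMaterial:
    """Seeds for the server (OTP) and site (partitioned) noise matrices."""

    server_seeds: list[int]
    site_seeds: list[int]
    scale: float
    shape: tuple

    @classmethod
    def generate(
        cls, rng: np.random.Generator, J: int, shape: tuple, scale: float
    ) -> "MaskMaterial":
        seeds = rng.integers(0, 2**31 - 1, size=2 * J)
        return cls(
            server_seeds=[int(s) for s in seeds[:J]],
            site_seeds=[int(s) for s in seeds[J:]],
            scale=float(scale),
            shape=tuple(shape),
        )

    def server_noise(self, j: int) -> np.ndarray:
        rng = np.random.default_rng(self.server_seeds[j])
        return rng.normal(0.0, self.scale, size=self.shape)

    def partitioned_noise(self, j: int, plan: PartitionPlan) -> np.ndarray:
        return make_partitioned_noise(
            self.site_seeds[j], self.shape, plan.row_ranges[j], self.scale
        )


# ---------------------------------------------------------------------------
# encryption backends
# ---------------------------------------------------------------------------


@dataclass
class CipherBlock:
    """Opaque additively combinable encrypted matrix."""

    payload: np.ndarray
    shape: tuple
    backend_id: str
    mask_ids: tuple = ()
    tag: int = 0


class EncryptionBackend:
    """Contract: keygen / encrypt / add / decrypt with additive homomorphism."""

    backend_id = "abstract"
    tolerance = 0.0

    def keygen(self):  # -> (public_key, private_key)
        raise NotImplementedError

    def encrypt(self, M: np.ndarray, public_key) -> CipherBlock:
        raise NotImplementedError

    def add(self, a: CipherBlock, b: CipherBlock) -> CipherBlock:
        if a.shape != b.shape or a.backend_id != b.backend_id:
            raise ValueError("incompatible cipher blocks")
        return CipherBlock(
            payload=a.payload + b.payload,
            shape=a.shape,
            backend_id=a.backend_id,
            mask_ids=a.mask_ids + b.mask_ids,
            tag=a.tag ^ b.tag,
        )

    def decrypt(self, block: CipherBlock, private_key) -> np.ndarray:
        raise NotImplementedError


class MaskBackend(EncryptionBackend):
    """OTP-like symmetric scheme: encryption is addition of seeded noise.

    Each ``encrypt`` draws a fresh pad from a seed derived from the private
    key material and a per-call counter (the pad's identity travels in the
    cipher block); ``decrypt`` regenerates and subtracts every pad present
    in the aggregate.  Cancellation is exact up to float64 addition error,
    so the tolerance scales with the pad magnitude.
    """

    backend_id = "mask"

    def __init__(
        self, scale: float = DEFAULT_MASK_SCALE, rng: np.random.Generator | None = None
    ) -> None:
        self.scale = float(scale)
        self.tolerance = self.scale * 1e-9
        self.rng = rng

    def keygen(self):
        rng = self.rng if self.rng is not None else np.random.default_rng()
        root = rng.integers(0, 2**31 - 1)
        key = {"root": int(root), "counter": [0]}
        return key, key  # symmetric: public and private material coincide

    def _pad(self, key, mask_id: int, shape: tuple) -> np.ndarray:
        rng = np.random.default_rng((key["root"], mask_id))
        return rng.normal(0.0, self.scale, size=shape)

    def encrypt(self, M: np.ndarray, public_key) -> CipherBlock:
        M = np.asarray(M, dtype=float)
        mask_id = public_key["counter"][0]
        public_key["counter"][0] += 1
        pad = self._pad(public_key, mask_id, M.shape)
        return CipherBlock(
            payload=M + pad,
            shape=M.shape,
            backend_id=self.backend_id,
            mask_ids=(mask_id,),
        )

    def decrypt(self, block: CipherBlock, private_key) -> np.ndarray:
        out = block.payload.copy()
        for mid in block.mask_ids:
            out -= self._pad(private_key, mid, block.shape)
        return out


class MockHEBackend(EncryptionBackend):
    """Plaintext stand-in honoring the additive-backend contract.

    ``encrypt`` copies the matrix and attaches a random session tag so that
    serialized blocks differ between sessions; arithmetic is exact.
    """

    backend_id = "mock-he"
    tolerance = 1e-12

    def __init__(self, rng: np.random.Generator | None = None) -> None:
        self.rng = rng

    def keygen(self):
        rng = self.rng if self.rng is not None else np.random.default_rng()
        return int(rng.integers(0, 2**31 - 1)), int(rng.integers(0, 2**31 - 1))

    def encrypt(self, M: np.ndarray, public_key) -> CipherBlock:
        M = np.asarray(M, dtype=float)
        rng = self.rng if self.rng is not None else np.random.default_rng()
        tag = int(rng.integers(0, 2**31 - 1))
        return CipherBlock(
            payload=M.copy(), shape=M.shape, backend_id=self.backend_id, tag=tag
        )

    def decrypt(self, block: CipherBlock, private_key) -> np.ndarray:
        return block.payload.copy()


_BACKENDS: dict[str, type[EncryptionBackend]] = {
    "mask": MaskBackend,
    "mock-he": MockHEBackend,
}


def register_backend(name: str, cls: type[EncryptionBackend]) -> None:
    """Register an additional backend (e.g. a real lattice-based plugin)."""
    _BACKENDS[name] = cls


def get_backend(name: str, **kwargs) -> EncryptionBackend:
    try:
        return _BACKENDS[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None


# ---------------------------------------------------------------------------
# aggregation protocols
# ---------------------------------------------------------------------------


def round_robin_secure_sum(
    shares: list[np.ndarray],
    backend: EncryptionBackend,
    keys=None,
    transcript: Transcript | None = None,
    kind: str = "aggregate",
    stage: str = "",
) -> np.ndarray:
    """Sites take turns adding their encrypted share; server decrypts the sum.

    Intermediate hops only ever see cipher blocks.  Returns the plaintext
    aggregate as visible at the server.
    """
    if not shares:
        raise ValueError("no shares to aggregate")
    shapes = {np.asarray(s).shape for s in shares}
    if len(shapes) != 1:
        raise ValueError(f"non-uniform share shapes: {shapes}")
    pk, sk = keys if keys is not None else backend.keygen()
    acc = None
    J = len(shares)
    for j, share in enumerate(shares):
        block = backend.encrypt(np.asarray(share, dtype=float), pk)
        acc = block if acc is None else backend.add(acc, block)
        if transcript is not None:
            nxt = f"site{j + 1}" if j < J - 1 else "server"
            transcript.log(f"site{j}", nxt, kind, block.shape, True, stage)
    out = backend.decrypt(acc, sk)
    err_scale = max(1.0, float(np.max(np.abs(out))))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("decryption produced non-finite aggregate")
    if backend.tolerance and backend.tolerance > 1e6 * err_scale:
        raise ValueError("backend tolerance too loose for this aggregate")
    return out


@dataclass
class EadpResult:
    """Output of one encrypt-aggregate-decrypt-partition round."""

    partitions: list[np.ndarray]  # clean per-site row slices of the sum
    server_visible: np.ndarray  # what the server saw: sum + total part. noise
    masks: MaskMaterial


def eadp(
    local_matrices: list[np.ndarray],
    plan: PartitionPlan,
    masks: MaskMaterial | None = None,
    backend: EncryptionBackend | None = None,
    keys=None,
    rng: np.random.Generator | None = None,
    transcript: Transcript | None = None,
    kind: str = "eadp",
    stage: str = "",
) -> EadpResult:
    """Encrypt-aggregate-decrypt-partition.

    Site j adds its partitioned noise N_(j)^(part) to its full-shape share,
    encrypts, and the shares are round-robin summed.  The server decrypts,
    obtaining  sum_j shares + sum_j N_(j)^(part)  — it cannot strip the
    partitioned noise — then returns row slice j to site j, which removes
    its own noise.  Returns the clean partitions plus the server-visible
    aggregate for auditing.
    """
    J = plan.J
    if len(local_matrices) != J:
        missing = J - len(local_matrices)
        raise ValueError(f"expected one share per site; {missing} missing")
    mats = [np.asarray(m, dtype=float) for m in local_matrices]
    shape = mats[0].shape
    for j, m in enumerate(mats):
        if m.shape != shape:
            raise ValueError(f"site {j} share has shape {m.shape}, expected {shape}")
    backend = backend or MaskBackend()
    if masks is None:
        scale = DEFAULT_MASK_SCALE * max(
            1.0, max(float(np.max(np.abs(m))) for m in mats)
        )
        rng = rng or np.random.default_rng()
        masks = MaskMaterial.generate(rng, J, shape, scale)
    noisy = [
        mats[j] + masks.partitioned_noise(j, plan) for j in range(J)
    ]
    server_visible = round_robin_secure_sum(
        noisy, backend, keys=keys, transcript=transcript, kind=kind, stage=stage
    )
    partitions = []
    for j in range(J):
        lo, hi = plan.row_ranges[j]
        own_noise = masks.partitioned_noise(j, plan)[lo:hi]
        if transcript is not None:
            transcript.log(
                "server", f"site{j}", f"{kind}-partition", (hi - lo,) + shape[1:],
                True, stage,
            )
        partitions.append(server_visible[lo:hi] - own_noise)
    return EadpResult(partitions=partitions, server_visible=server_visible, masks=masks)


# ---------------------------------------------------------------------------
# rotation masking for the projection matrix
# ---------------------------------------------------------------------------


@dataclass
class RotationSecret:
    """Shared invertible p x p rotation Q (site-side secret, never at server)."""

    Q: np.ndarray
    Q_inv: np.ndarray

    @classmethod
    def generate(
        cls,
        p: int,
        n: int,
        rng: np.random.Generator,
        cond_max: float = 1e6,
        max_retries: int = 20,
    ) -> "RotationSecret":
        """Entries i.i.d. N(0, variance n); regenerate if ill-conditioned."""
        for _ in range(max_retries):
            Q = rng.normal(0.0, np.sqrt(n), size=(p, p))
            if np.linalg.cond(Q) <= cond_max:
                return cls(Q=Q, Q_inv=np.linalg.inv(Q))
        raise RuntimeError(
            f"failed to draw a well-conditioned Q in {max_retries} tries"
        )


def rotation_mask_products(
    Omega_j: np.ndarray, Xi_inv: np.ndarray, secret: RotationSecret
) -> tuple[np.ndarray, np.ndarray]:
    """Site-side rotated shares A_j = Omega_j Q and B_j = Q^{-1} Xi^{-1} Omega_j'.

    Summed over sites, (sum A_j)(sum B_j) = Omega Xi^{-1} Omega' exactly
    (the rotations cancel), letting the server assemble
    P = Sigma^{-1} - Omega Xi^{-1} Omega' without learning Omega.
    """
    A = Omega_j @ secret.Q
    B = secret.Q_inv @ (Xi_inv @ Omega_j.T)
    return A, B


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


def quantize_matrix(M: np.ndarray, precision: int) -> np.ndarray:
    """Round-trip a matrix through the given float precision (64 or 32)."""
    M = np.asarray(M, dtype=float)
    if precision == 64:
        return M.copy()
    if precision != 32:
        raise ValueError("precision must be 32 or 64")
    limit = float(np.finfo(np.float32).max)
    big = np.abs(M) > limit
    if big.any():
        raise OverflowError(
            f"entry magnitude {np.abs(M).max():.3e} exceeds float32 range"
        )
    return M.astype(np.float32).astype(np.float64)
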