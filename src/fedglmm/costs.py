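"""Network/storage cost estimator for the federated protocol.

Enumerates every inter-party transfer of the three protocol stages and
sizes it in mebibytes (2^20 bytes, 8-byte float64 elements; 4 bytes when
quantized).  Per-site dimensions use the fractional n_j = n/J so that the
reported sizes are the exact per-client averages; the homomorphic-
encryption column scales plaintext sizes by a ciphertext expansion factor
(default 13.5, the midpoint of the observed 12-15x range).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

DEFAULT_HE_EXPANSION = 13.5


def matrix_transfer_mib(rows: float, cols: float, bytes_per_element: int = 8) -> float:
    """Size of a rows x cols matrix transfer in MiB (2^20 bytes)."""
    if rows < 0 or cols < 0 or bytes_per_element < 0:
        raise ValueError("dimensions must be nonnegative")
    return rows * cols * bytes_per_element / 2**20


@dataclass
class CostRow:
    stage: str
    direction: str  # "client->server" or "server->client"
    payload: str
    dims: str
    per_iteration: bool
    count: float  # how many times this message is sent per client
    mib: float  # plaintext MiB per single message
    mib_he: float

    @property
    def total_mib(self) -> float:
        return self.count * self.mib

    @property
    def total_mib_he(self) -> float:
        return self.count * self.mib_he


@dataclass
class CostReport:
    params: dict
    rows: list[CostRow] = field(default_factory=list)

    def stage_total(self, stage: str, he: bool = False) -> float:
        return sum(
            (r.total_mib_he if he else r.total_mib)
            for r in self.rows
            if r.stage == stage
        )

    @property
    def total_mib(self) -> float:
        return sum(r.total_mib for r in self.rows)

    @property
    def total_mib_he(self) -> float:
        return sum(r.total_mib_he for r in self.rows)

    def find(self, payload: str) -> CostRow:
        for r in self.rows:
            if r.payload == payload:
                return r
        raise KeyError(payload)

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params,
                "rows": [
                    {
                        "stage": r.stage,
                        "direction": r.direction,
                        "payload": r.payload,
                        "dims": r.dims,
                        "count": r.count,
                        "mib": round(r.mib, 4),
                        "mib_he": round(r.mib_he, 4),
                        "total_mib": round(r.total_mib, 4),
                    }
                    for r in self.rows
                ],
                "totals": {
                    "plaintext_mib": round(self.total_mib, 4),
                    "he_mib": round(self.total_mib_he, 4),
                },
            },
            indent=1,
        )

    def format_table(self) -> str:
        lines = [
            f"{'stage':<12}{'direction':<18}{'payload':<28}{'dims':<16}"
            f"{'MiB':>14}{'MiB (HE)':>14}"
        ]
        for r in self.rows:
            lines.append(
                f"{r.stage:<12}{r.direction:<18}{r.payload:<28}{r.dims:<16}"
                f"{r.mib:>14.4f}{r.mib_he:>14.4f}"
            )
        lines.append(
            f"{'TOTAL':<74}{self.total_mib:>14.4f}{self.total_mib_he:>14.4f}"
        )
        return "\n".join(lines)


def protocol_cost_report(
    n: int,
    p: int,
    J: int = 3,
    n_snps: int = 1_000_000,
    chunk_k: int = 200,
    n_iters: int = 12,
    he_expansion: float = DEFAULT_HE_EXPANSION,
    quantized: bool = False,
) -> CostReport:
    """Per-client network traffic of the full protocol.

    ``p`` counts the intercept plus covariates.  Per-message sizes use
    fractional n_j = n/J; the per-client count multiplies in iterations and
    chunks.  ``quantized`` switches large-matrix transfers to 4 bytes.
    """
    if min(n, p, J, n_snps, chunk_k, n_iters) <= 0:
        raise ValueError("all parameters must be positive")
    nj = n / J
    bpe = 4 if quantized else 8
    n_chunks = n_snps / chunk_k
    rows: list[CostRow] = []

    def add(stage, direction, payload, r, c, dims, count, bytes_=8):
        mib = matrix_transfer_mib(r, c, bytes_)
        rows.append(
            CostRow(
                stage=stage, direction=direction, payload=payload, dims=dims,
                per_iteration=count > 1, count=count, mib=mib,
                mib_he=mib * he_expansion,
            )
        )

    it = float(n_iters)
    # --- stage 1: Newton initialization ---
    add("null", "client->server", "gradient", p, 1, "p", it)
    add("null", "client->server", "hessian", p, p, "p x p", it)
    add("null", "server->client", "alpha", p, 1, "p", it)
    # --- stage 2: PQL / mixed model ---
    add("mixed", "client->server", "Xi", p, p, "p x p", it)
    add("mixed", "client->server", "Omega", n, p, "n x p", it)
    add("mixed", "client->server", "bhat", n, 1, "n", it)
    add("mixed", "server->client", "VSigma_inv_part", n, nj, "n x n_j", it, bpe)
    add("mixed", "server->client", "Sigma_inv_part", n, nj, "n x n_j", it, bpe)
    add("mixed", "server->client", "b", n, 1, "n", it)
    add("mixed", "server->client", "tau", 1, 1, "scalar", it)
    # --- stage 3: score test ---
    add("score", "client->server", "score_T", n_snps, 1, "n_snps", 1.0)
    add("score", "client->server", "GtP", chunk_k, n, "k x n", n_chunks, bpe)
    add("score", "client->server", "GtPG", chunk_k, chunk_k, "k x k", n_chunks)
    add("score", "server->client", "PYtilde_part", nj, 1, "n_j", 1.0)
    add("score", "server->client", "P_part", n, nj, "n x n_j", 1.0, bpe)
    add("score", "server->client", "GtP_part", chunk_k, nj, "k x n_j", n_chunks, bpe)
    return CostReport(
        params={
            "n": n, "p": p, "J": J, "n_snps": n_snps, "chunk_k": chunk_k,
            "n_iters": n_iters, "he_expansion": he_expansion, "quantized": quantized,
        },
        rows=rows,
    )
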