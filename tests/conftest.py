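import numpy as np
import pandas as pd
import pytest

from chemoscreen.io import CountMatrix


def build_counts(count_cols: dict, gene_ids: list, sheet_rows: list, controls: set = frozenset()) -> CountMatrix:
    """Assemble a CountMatrix from per-sample count lists.

    ``sheet_rows`` are (sample_id, arm, compound, bio_rep, tech_rep) tuples;
    guide ids are g1..gn, mapped in order onto ``gene_ids``.
    """
    n = len(gene_ids)
    guide_ids = [f"g{i + 1}" for i in range(n)]
    library = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "gene_id": gene_ids,
            "is_control": [g in controls for g in gene_ids],
        }
    )
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "arm", "compound", "bio_rep", "tech_rep"])
    counts = pd.DataFrame(
        {s: np.asarray(count_cols[s], dtype=np.int64) for s in sheet["sample_id"]},
        index=pd.Index(guide_ids, name="guide_id"),
    )
    return CountMatrix(library=library, samples=sheet, counts=counts)


@pytest.fixture
def tiny_screen() -> CountMatrix:
    """2 genes x 2 guides + 1 control guide; T0 / mock / treated, one bio rep."""
    return build_counts(
        count_cols={
            "t0": [100, 100, 100, 100, 100],
            "mock_1": [100, 120, 90, 100, 110],
            "drug_1": [400, 380, 50, 45, 105],
        },
        gene_ids=["GA", "GA", "GB", "GB", "CTRL1"],
        sheet_rows=[
            ("t0", "T0", None, 1, 1),
            ("mock_1", "mock", None, 1, 1),
            ("drug_1", "treated", "drug", 1, 1),
        ],
        controls={"CTRL1"},
    )


def residual_frame(A, M, compound: str = "c", gene_size: int = 1) -> pd.DataFrame:
    """Residual table over one compound with synthetic guide/gene labels."""
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    n = len(A)
    return pd.DataFrame(
        {
            "guide_id": [f"g{i}" for i in range(n)],
            "gene_id": [f"G{i // gene_size}" for i in range(n)],
            "compound": compound,
            "bio_rep": 1,
            "M": M,
            "A": A,
            "M_norm": np.nan,
        }
    )


def loess_oracle(x: np.ndarray, y: np.ndarray, frac: float) -> np.ndarray:
    """Brute-force per-point tricube weighted-least-squares smoother.

    For each point: take the span-fraction nearest neighbours, tricube
    weights scaled by the k-th nearest distance, degree-1 weighted fit,
    predict at the point. Independent of the production smoother.
    """
    n = len(x)
    k = int(frac * n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[k - 1]
        w = np.clip(1.0 - (d / max(h, 1e-300)) ** 3, 0.0, 1.0) ** 3
        X = np.vstack([np.ones(n), x]).T
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        fitted[i] = beta[0] + beta[1] * x[i]
    return fitted
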