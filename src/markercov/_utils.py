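"""Small shared helpers: rounding, sparse coercion, validation."""

from __future__ import annotations

import decimal

import numpy as np
import scipy.sparse as sp

MITO_PREFIX = "MT-"
HEMOGLOBIN_PREFIX = "HB"


def round_half_up(x, ndigits: int = 2):
    """Round with ties away from zero, matching printed-table conventions.

    numpy/python round half-to-even; percentage-style exports here use
    half-up, so 2.345 -> 2.35 at 2 dp.
    """
    if np.ndim(x) > 0:
        return np.array([round_half_up(v, ndigits) for v in np.asarray(x).ravel()]).reshape(
            np.shape(x)
        )
    if not np.isfinite(x):
        return float(x)
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def as_csr(X) -> sp.csr_matrix:
    """Coerce a dense/sparse matrix to CSR without copying when possible."""
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X))


def check_nonnegative_integers(X) -> bool:
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size == 0:
        return True
    return bool(np.all(data >= 0) and np.all(np.equal(np.mod(data, 1), 0)))


def gene_flags_from_names(gene_ids) -> tuple[np.ndarray, np.ndarray]:
    """Derive (is_mito, is_hemoglobin) boolean arrays from identifier prefixes."""
    names = np.asarray(gene_ids, dtype=object)
    is_mito = np.array([str(g).upper().startswith(MITO_PREFIX) for g in names])
    is_hb = np.array(
        [str(g).upper().startswith(HEMOGLOBIN_PREFIX) and not str(g).upper().startswith(MITO_PREFIX)
         for g in names]
    )
    return is_mito, is_hb
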