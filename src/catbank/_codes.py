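"""Response-matrix conventions shared across the pipeline.

Responses are persons x items matrices of ordinal codes 0..K-1 stored as
floats.  Two kinds of unobserved cell exist: plain missing (NaN) and an
explicit "not applicable" choice (code -1).  Both are excluded from every
likelihood and statistic downstream; they are distinguished only on disk
(missing -> empty cell, NA -> "NA_APPLICABLE").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NOT_APPLICABLE = -1.0
NA_TOKEN = "NA_APPLICABLE"


def as_matrix(responses) -> np.ndarray:
    """Coerce a DataFrame or array of response codes to a float ndarray."""
    if isinstance(responses, pd.DataFrame):
        return responses.to_numpy(dtype=float)
    return np.asarray(responses, dtype=float)


def observed_mask(responses) -> np.ndarray:
    """True where a cell holds a real response (not missing, not NA)."""
    x = as_matrix(responses)
    return np.isfinite(x) & (x != NOT_APPLICABLE)


def coded(responses) -> np.ndarray:
    """Integer codes with -9 marking any unobserved cell."""
    x = as_matrix(responses)
    obs = observed_mask(x)
    out = np.full(x.shape, -9, dtype=int)
    out[obs] = x[obs].astype(int)
    return out


def write_responses_csv(responses: pd.DataFrame, path) -> None:
    arr = as_matrix(responses)
    obs = observed_mask(arr)
    na = np.isfinite(arr) & (arr < 0)
    cells = np.full(arr.shape, "", dtype=object)
    cells[obs] = [str(int(v)) for v in arr[obs]]
    cells[na] = NA_TOKEN
    cols = list(responses.columns) if isinstance(responses, pd.DataFrame) else None
    pd.DataFrame(cells, columns=cols).to_csv(path, index=False)


def read_responses_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    def cell(v: str) -> float:
        if v == "":
            return np.nan
        if v == NA_TOKEN:
            return NOT_APPLICABLE
        return float(v)
    return raw.map(cell)
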