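"""Reading, writing, normalizing and simulating concentration-response data.

Tables are delimited text with a header; concentrations may be given in
molar or as log10(molar).  Raw current ratios I/I0 are normalized to
dI/dImax by subtracting the baseline and dividing by the largest increase.
The module also embeds, verbatim, the published ztz240/KCNQ2 dataset used
throughout the package (wild-type and 1:1 WT–F137A heteromeric channels,
mean ± SEM over cells), and provides a forward-model simulator for
generating synthetic datasets with additive Gaussian noise.
"""

from __future__ import annotations

import io
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .thermo import DegeneracyVector, ThermoParams, response

__all__ = [
    "read_response_table",
    "write_response_table",
    "dataset_to_json",
    "dataset_from_json",
    "normalize",
    "table1_fixture",
    "table1_heteromer_prediction",
    "simulate_dataset",
]

# Published concentration-response table for ztz240 on KCNQ2 (mean, SEM).
# Stored digit-for-digit as printed; the normalized column is authoritative
# (per-cell normalization upstream means it is not exactly the aggregate
# (I/I0 - 1)/max formula applied to the printed means).
_TABLE1_WT = {
    "log10_concentration": (-8.0, -7.0, -6.0, -5.5, -5.0, -4.0),
    "i_over_i0": (1.03, 1.09, 1.20, 1.35, 1.90, 2.43),
    "i_over_i0_sem": (0.03, 0.09, 0.09, 0.2, 0.4, 0.5),
    "normalized": (0.0210, 0.0636, 0.139, 0.245, 0.627, 1.00),
    "normalized_sem": (0.02, 0.06, 0.06, 0.2, 0.3, 0.3),
}

_TABLE1_HETEROMER = {
    "log10_concentration": (-8.0, -7.0, -6.0, -5.5, -5.0, -4.0, -3.5),
    "i_over_i0": (1.02, 1.12, 1.29, 1.13, 1.48, 2.12, 2.33),
    "i_over_i0_sem": (0.01, 0.08, 0.07, 0.02, 0.07, 0.1, 0.3),
    "normalized": (0.0150, 0.0902, 0.218, 0.0977, 0.361, 0.842, 1.00),
    "normalized_sem": (0.008, 0.06, 0.05, 0.02, 0.05, 0.09, 0.2),
    "predicted": (0.00866, 0.0750, 0.231, 0.275, 0.359, 0.911, 0.981),
}

_CONC_COLUMNS = ("concentration_M", "concentration", "conc_M", "conc")
_LOG10_COLUMNS = ("log10_conc", "log10_concentration", "log_conc")
_RESPONSE_COLUMNS = ("response", "normalized", "delta_i_norm", "dI_dImax")
_RATIO_COLUMNS = ("i_over_i0", "ratio", "I_I0")
_SEM_COLUMNS = ("sem", "SEM", "stderr")


def _resolve(columns, requested, candidates):
    if requested is not None:
        if requested not in columns:
            raise ValueError(f"column {requested!r} not found in {list(columns)}")
        return requested
    for c in candidates:
        if c in columns:
            return c
    return None


def read_response_table(
    source: Union[str, Path, io.IOBase],
    *,
    delimiter: str = ",",
    concentration_column: Optional[str] = None,
    log10_column: Optional[str] = None,
    response_column: Optional[str] = None,
    ratio_column: Optional[str] = None,
    sem_column: Optional[str] = None,
    allow_shrinking_ratios: bool = False,
    label: str = "",
):
    """Read a delimited concentration-response table into a ResponseDataset.

    The file must have a header row.  Concentrations are taken from a molar
    column or a log10(molar) column (exactly one must be present); the
    response is taken from a normalized-response column if present, else
    computed by :func:`normalize` from a raw I/I0 column.  Rows are sorted
    by ascending concentration.  Malformed cells and duplicate
    concentrations raise errors naming the offending rows.
    """
    from .fitting import ResponseDataset

    df = pd.read_csv(source, sep=delimiter, dtype=str, skipinitialspace=True)
    df = df.dropna(how="all")
    if df.shape[0] == 0:
        raise ValueError("no data rows in input table")
    df.columns = [c.strip() for c in df.columns]

    conc_col = _resolve(df.columns, concentration_column, _CONC_COLUMNS)
    log_col = _resolve(df.columns, log10_column, _LOG10_COLUMNS)
    if (conc_col is None) == (log_col is None):
        raise ValueError(
            "exactly one concentration column is required: molar "
            f"({'/'.join(_CONC_COLUMNS)}) or log10 ({'/'.join(_LOG10_COLUMNS)}); "
            f"found columns {list(df.columns)}"
        )
    resp_col = _resolve(df.columns, response_column, _RESPONSE_COLUMNS)
    ratio_col = _resolve(df.columns, ratio_column, _RATIO_COLUMNS)
    if resp_col is None and ratio_col is None:
        raise ValueError(
            "no response column found: need one of "
            f"{_RESPONSE_COLUMNS} or a raw ratio column {_RATIO_COLUMNS}"
        )
    sem_col = _resolve(df.columns, sem_column, _SEM_COLUMNS)

    def numeric(col):
        # parse with Python's float for exact (correctly rounded) doubles
        vals, bad = [], []
        for idx, cell in df[col].items():
            try:
                vals.append(float(cell))
            except (TypeError, ValueError):
                bad.append(idx)
        if bad:
            rows = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
            raise ValueError(f"non-numeric values in column {col!r} at file rows {rows}")
        return np.asarray(vals, dtype=float)

    conc = 10.0 ** numeric(log_col) if conc_col is None else numeric(conc_col)
    dup = pd.Series(conc).duplicated(keep=False)
    if dup.any():
        offenders = sorted(set(conc[dup.to_numpy()]))
        raise ValueError(
            "duplicate concentrations: " + ", ".join(f"{c:g} M" for c in offenders)
        )

    ratio = numeric(ratio_col) if ratio_col is not None else None
    if resp_col is not None:
        resp = numeric(resp_col)
    else:
        resp = np.asarray(normalize(ratio, allow_below_one=allow_shrinking_ratios))
    sem = numeric(sem_col) if sem_col is not None else None

    order = np.argsort(conc)
    return ResponseDataset(
        concentrations=conc[order],
        responses=resp[order],
        sem=None if sem is None else sem[order],
        raw_ratio=None if ratio is None else ratio[order],
        label=label,
    )


def write_response_table(dataset, path: Union[str, Path], *, delimiter: str = ",") -> None:
    """Write a ResponseDataset as delimited text (full float precision).

    Only the molar concentration column is written, so the file satisfies
    the one-concentration-representation rule and round-trips through
    :func:`read_response_table` exactly.
    """
    df = dataset.to_frame().drop(columns=["log10_conc"])
    # 17 significant digits round-trip any double exactly
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def dataset_to_json(dataset, path: Union[str, Path], metadata: Optional[dict] = None) -> None:
    """Serialize a dataset (plus provenance metadata) to JSON."""
    doc = {
        "tool": "tetrafit",
        "version": _version,
        "label": dataset.label,
        "concentration_M": dataset.concentrations.tolist(),
        "response": dataset.responses.tolist(),
        "sem": None if dataset.sem is None else dataset.sem.tolist(),
        "i_over_i0": None if dataset.raw_ratio is None else dataset.raw_ratio.tolist(),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def dataset_from_json(path: Union[str, Path]):
    from .fitting import ResponseDataset

    doc = json.loads(Path(path).read_text())
    return ResponseDataset(
        concentrations=np.asarray(doc["concentration_M"], dtype=float),
        responses=np.asarray(doc["response"], dtype=float),
        sem=None if doc.get("sem") is None else np.asarray(doc["sem"], dtype=float),
        raw_ratio=None if doc.get("i_over_i0") is None
        else np.asarray(doc["i_over_i0"], dtype=float),
        label=doc.get("label", ""),
    )


def normalize(ratios: Sequence[float], *, allow_below_one: bool = False) -> list[float]:
    """Normalize raw current ratios I/I0 to dI/dImax.

    dI_i = ratio_i - 1 (the concentration-induced current increase), divided
    by the largest increase so the maximum maps to 1.  Ratios below 1 mean
    the current shrank; they are rejected unless ``allow_below_one``.
    """
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("ratios must be a non-empty 1-D sequence")
    if not allow_below_one and np.any(r < 1.0):
        raise ValueError(
            "ratios below 1 (current inhibition) present; pass "
            "allow_below_one=True to accept them"
        )
    delta = r - 1.0
    peak = delta.max()
    if peak <= 0:
        raise ValueError("all ratios <= 1: normalization is undefined")
    return list(delta / peak)


def table1_fixture(channel: str = "wt"):
    """The embedded published dataset for ztz240 potentiating KCNQ2.

    ``channel="wt"`` gives the six-point wild-type table, ``"heteromeric"``
    the seven-point 1:1 WT–F137A table.  The printed normalized column is
    returned as the response (it is the fitting target); the raw I/I0 means
    ride along in ``raw_ratio``.
    """
    from .fitting import ResponseDataset

    try:
        tab = {"wt": _TABLE1_WT, "heteromeric": _TABLE1_HETEROMER}[channel]
    except KeyError:
        raise ValueError(f"channel must be 'wt' or 'heteromeric', got {channel!r}")
    return ResponseDataset(
        concentrations=10.0 ** np.asarray(tab["log10_concentration"]),
        responses=np.asarray(tab["normalized"], dtype=float),
        sem=np.asarray(tab["normalized_sem"], dtype=float),
        raw_ratio=np.asarray(tab["i_over_i0"], dtype=float),
        label=f"ztz240/KCNQ2 {channel}",
    )


def table1_heteromer_prediction() -> pd.DataFrame:
    """The published model-predicted heteromeric responses (Pred. column)."""
    tab = _TABLE1_HETEROMER
    return pd.DataFrame(
        {
            "log10_conc": tab["log10_concentration"],
            "concentration_M": 10.0 ** np.asarray(tab["log10_concentration"]),
            "predicted": tab["predicted"],
        }
    )


def simulate_dataset(
    params: ThermoParams,
    degeneracies: DegeneracyVector,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    label: str = "synthetic",
):
    """Generate a synthetic dataset from the forward model.

    Each replicate adds independent Gaussian noise of standard deviation
    ``noise_sd`` to the model response; the dataset holds the per-point
    replicate mean with the sample SEM attached (when replicates > 1).
    Deterministic for a given seed.
    """
    from .fitting import ResponseDataset

    conc = np.sort(np.asarray(list(concentrations), dtype=float))
    if conc.size == 0:
        raise ValueError("need at least one concentration")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0 M")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truth = response(params, degeneracies, conc)
    rng = np.random.default_rng(seed)
    draws = truth[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, conc.size))
    mean = draws.mean(axis=0)
    sem = (
        draws.std(axis=0, ddof=1) / np.sqrt(n_replicates)
        if n_replicates > 1
        else None
    )
    return ResponseDataset(
        concentrations=conc, responses=mean, sem=sem, label=label
    )
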