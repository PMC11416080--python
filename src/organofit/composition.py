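"""Cell-type composition comparison between paired primary and organoid samples.

Organoid culture enriches the epithelial compartment and depletes immune and
stromal cells; this module quantifies that shift as per-patient log2 fold
changes of cell-type proportions (organoid over primary) and tests, per cell
type, whether the mean fold change across patients differs from zero with a
one-sample t-test, Benjamini-Hochberg adjusted across cell types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import OrganofitError


def proportions(cells: pd.DataFrame, cell_types: list[str] | None = None) -> pd.DataFrame:
    """Per-(patient, source) cell-type proportions.

    ``cells`` needs ``patient``, ``source`` and ``cell_type`` columns.
    Returns a frame indexed by (patient, source) with one column per cell
    type; rows sum to 1.
    """
    if "cell_type" not in cells.columns:
        raise OrganofitError("cells lack a cell_type column; run annotate_cell_types")
    tab = pd.crosstab([cells["patient"], cells["source"]], cells["cell_type"])
    if cell_types is not None:
        tab = tab.reindex(columns=cell_types, fill_value=0)
    props = tab.div(tab.sum(axis=1), axis=0)
    props.index.names = ["patient", "source"]
    return props


def fold_change_test(
    props: pd.DataFrame, epsilon: float = 1e-3
) -> pd.DataFrame:
    """One-sample t-tests of per-patient log2 fold changes against zero.

    For each patient with both sources, ``FC = log2((p_BCO + eps) /
    (p_PBC + eps))`` per cell type; the pseudo-proportion ``eps`` guards the
    log when a compartment is absent from one source.  Zero variance across
    patients leaves p undefined (NaN) with a flag.
    """
    pbc = props.xs("PBC", level="source")
    bco = props.xs("BCO", level="source")
    patients = pbc.index.intersection(bco.index)
    if len(patients) < 2:
        raise OrganofitError("need >= 2 patients with both sources")
    fc = np.log2((bco.loc[patients] + epsilon) / (pbc.loc[patients] + epsilon))

    rows = []
    for ct in fc.columns:
        x = fc[ct].to_numpy(dtype=float)
        n = len(x)
        mean = float(x.mean())
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        sd = float(x.std(ddof=1))
        flag = ""
        if sd == 0.0:
            t_stat, p = (0.0, np.nan) if mean == 0 else (np.inf * np.sign(mean), 0.0)
            if mean == 0:
                flag = "zero_variance"
        else:
            t_stat, p = stats.ttest_1samp(x, 0.0)
        rows.append(
            {
                "cell_type": ct,
                "n_patients": n,
                "mean_fc": mean,
                "median_fc": float(med),
                "iqr": float(q3 - q1),
                "t": float(t_stat),
                "df": n - 1,
                "p": float(p) if np.isfinite(p) else np.nan,
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    defined = out["p"].notna().to_numpy()
    padj = np.full(len(out), np.nan)
    if defined.any():
        padj[defined] = multipletests(out.loc[defined, "p"], method="fdr_bh")[1]
    out["p_adj"] = padj
    return out
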