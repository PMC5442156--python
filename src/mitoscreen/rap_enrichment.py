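"""RNA-pulldown proteomics scoring.

iBAQ (intensity-based absolute quantification) per protein: the sum of all
peptide peak intensities divided by the number of theoretically observable
tryptic peptides.  Proteins enriched in the target pulldown are called by a
pseudocount-stabilised log2 ratio against the mean of the control
pulldowns; the enriched set is then scanned for over-represented
annotation terms with a hypergeometric upper-tail test and
Benjamini-Hochberg correction.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def compute_ibaq(intensities: Sequence[float], n_theoretical: int) -> float:
    """iBAQ = sum(peptide intensities) / n theoretically observable peptides."""
    if n_theoretical < 1:
        raise ValueError("n_theoretical must be >= 1")
    vals = np.asarray(list(intensities), dtype=float)
    if vals.size and (vals < 0).any():
        raise ValueError("peptide intensities must be non-negative")
    return float(vals.sum()) / n_theoretical


def ibaq_table(peptides: pd.DataFrame, n_theoretical: Mapping[str, int]) -> pd.DataFrame:
    """Per-protein iBAQ from a peptide table (protein_id, peptide_id, intensity).

    Proteins present in ``n_theoretical`` but without peptides get iBAQ 0.
    """
    sums = peptides.groupby("protein_id")["intensity"].sum()
    rows = []
    for prot, n in n_theoretical.items():
        rows.append({
            "protein_id": prot,
            "ibaq": compute_ibaq([sums.get(prot, 0.0)], n),
            "n_theoretical": int(n),
        })
    return pd.DataFrame(rows)


def enriched_proteins(
    target: pd.DataFrame,
    controls: Sequence[pd.DataFrame],
    pseudocount: float = 1.0,
    min_log2: float = 1.0,
) -> pd.DataFrame:
    """Target-vs-control enrichment per protein.

    log2((target_iBAQ + pc) / (mean control_iBAQ + pc)); a protein is
    ``enriched`` when the ratio reaches ``min_log2`` *and* it was detected
    (iBAQ > 0) in the target pulldown.  Tables need columns protein_id,
    ibaq over a shared protein universe.
    """
    if len(controls) == 0:
        raise ValueError("at least one control pulldown is required")
    t = target.set_index("protein_id")["ibaq"]
    ctrl = pd.concat([c.set_index("protein_id")["ibaq"] for c in controls], axis=1)
    if ctrl.isna().any().any() or not t.index.equals(ctrl.index):
        ctrl = ctrl.reindex(t.index)
        if ctrl.isna().any().any():
            raise ValueError("control tables must cover the target protein universe")
    mean_ctrl = ctrl.mean(axis=1)
    log2_ratio = np.log2((t + pseudocount) / (mean_ctrl + pseudocount))
    return pd.DataFrame({
        "protein_id": t.index,
        "target_ibaq": t.to_numpy(),
        "mean_control_ibaq": mean_ctrl.to_numpy(),
        "log2_ratio": log2_ratio.to_numpy(),
        "enriched": ((log2_ratio >= min_log2) & (t > 0)).to_numpy(),
    }).reset_index(drop=True)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K term members, n drawn)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def term_enrichment(
    protein_set: Sequence[str],
    annotation: Mapping[str, set[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Over-representation of annotation terms within a protein set.

    Per term: k = members of the term in the set, K = term size within the
    universe, n = set size, N = universe size; hypergeometric upper-tail p
    with Benjamini-Hochberg FDR across all tested terms, sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hits = set(protein_set)
    if not hits <= uni:
        raise ValueError("protein set must be a subset of the universe")
    if not hits:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "fdr"])
    N, n = len(uni), len(hits)
    rows = []
    for term, members in annotation.items():
        mem = members & uni
        K = len(mem)
        if K == 0:
            continue
        k = len(mem & hits)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_upper_tail(k, K, n, N)})
    res = pd.DataFrame(rows)
    if res.empty:
        return res.reindex(columns=["term", "k", "K", "n", "N", "p", "fdr"])
    res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    return res.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
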