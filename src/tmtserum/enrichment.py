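"""Fisher-exact over-representation of annotation terms among regulated
features against the non-regulated background."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .datamodel import FormatError
from .diffexp import bh_adjust

log = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT-style annotation file: term, description, tab-separated members."""
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError("GMT lines need term, description and >= 1 member")
            term, desc, members = parts[0], parts[1], parts[2:]
            terms[term] = (desc, frozenset(m for m in members if m))
    return terms


def write_gmt(terms: dict[str, tuple[str, frozenset[str]]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc, members = terms[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def fisher_enrich(regulated: set, background: set,
                  annotations: dict, min_matches: int = 2,
                  adjp_threshold: float = 0.3) -> pd.DataFrame:
    """Two-sided Fisher exact over-representation analysis.

    For each term a 2x2 table {regulated, background} x {in term, not in
    term} is tested (two-sided: sum of hypergeometric probabilities no
    larger than the observed table's).  The background must be the
    *non-regulated* feature set, disjoint from the regulated one.  Terms
    matching fewer than ``min_matches`` regulated identifiers are not tested
    and are absent from the output; BH adjustment runs across tested terms
    only.  Sorted by adjusted p, then p, then term id.

    Returns columns: term, name, k (regulated in term), K (regulated total),
    n (background in term), N (background total), enrichment (k/K)/(n/N),
    direction, p, adj_p, significant.
    """
    regulated, background = set(regulated), set(background)
    if regulated & background:
        raise ValueError("regulated and background sets must be disjoint "
                         "(background = non-regulated features)")
    K, N = len(regulated), len(background)
    universe = regulated | background
    rows = []
    any_overlap = False
    for term, payload in annotations.items():
        if isinstance(payload, tuple):
            name, members = payload
        else:
            name, members = term, payload
        members = set(members)
        if members & universe:
            any_overlap = True
        k = len(members & regulated)
        if k < min_matches:
            continue
        n = len(members & background)
        odds, p = fisher_exact([[k, K - k], [n, N - n]], alternative="two-sided")
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = (k / K) / (n / N) if n > 0 and N > 0 else np.inf
        rows.append({
            "term": term, "name": name, "k": k, "K": K, "n": n, "N": N,
            "enrichment": float(enr),
            "direction": "over" if (n == 0 or k / K >= n / N) else "under",
            "p": float(p),
        })
    if not any_overlap:
        log.warning("annotation universe is disjoint from the analysed features")
    if not rows:
        return pd.DataFrame(columns=["term", "name", "k", "K", "n", "N",
                                     "enrichment", "direction", "p", "adj_p",
                                     "significant"])
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < adjp_threshold
    return out.sort_values(["adj_p", "p", "term"], kind="mergesort",
                           ignore_index=True)


def map_features_to_identifiers(features, groups: pd.Series,
                                group_to_id: dict | None = None) -> set:
    """Map features (peptides) to gene-level identifiers via protein groups.

    Each feature contributes its accession set, optionally translated by
    ``group_to_id`` (accession -> gene name); untranslated accessions pass
    through unchanged so synthetic accessions work as identifiers directly.
    """
    out = set()
    for f in features:
        for acc in groups.get(f, frozenset()):
            out.add(group_to_id.get(acc, acc) if group_to_id else acc)
    return out
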