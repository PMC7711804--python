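"""Proteome screening and enrichment statistics.

Reverse-vaccinology benchmarking runs the antigen predictor over a whole
bacterial proteome and asks how well the predicted set concentrates the
species' experimentally validated bacterial protective antigens (BPAs).
Four measures summarize a screen of a proteome of N proteins containing K
known BPAs, of which the predictor calls n potential vaccine candidates
(PVCs) covering k BPAs:

* PVC fraction n/N — how much of the proteome a vaccinologist must triage;
* BPA sensitivity k/K — how many known antigens the call set retains;
* fold-enrichment (k/K)/(n/N) — observed BPAs among PVCs over the count
  expected in a random same-size sample of the proteome;
* a hypergeometric upper-tail probability P(X >= k) for the significance of
  that enrichment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable

from scipy.stats import hypergeom

from .data import ProteinRecord
from .predictor import VaxiJenBundle, predict_batch

__all__ = [
    "ProteomeScreenResult",
    "normalize_protein_id",
    "fold_enrichment",
    "hypergeometric_pvalue",
    "screen_proteome",
    "screen_result_to_tsv",
    "combined_summary_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class ProteomeScreenResult:
    """Screening measures for one proteome."""

    proteome_name: str
    n_proteins: int            # N: admissible proteins screened
    n_pvc: int                 # n: predicted antigens (PVCs)
    pvc_fraction: float        # n / N
    n_bpa_total: int           # K: known BPAs among the screened proteins
    n_bpa_observed: int        # k: BPAs inside the PVC set
    bpa_sensitivity: float     # k / K
    fold_enrichment: float
    p_value: float
    n_skipped: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def normalize_protein_id(identifier: str) -> str:
    """Strip database prefixes (``sp|``, ``tr|``) down to the accession.

    ``sp|P12345|NAME_SPECIES`` and ``tr|Q67890|...`` both normalize to the
    central accession; anything else is returned unchanged.
    """
    parts = identifier.split("|")
    if len(parts) >= 2 and parts[0].lower() in ("sp", "tr"):
        return parts[1]
    return identifier


def fold_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Observed/expected BPA enrichment of the PVC set.

    ``(k/K) / (n/N)``: the number of BPAs observed among the n PVCs relative
    to the ``K*n/N`` expected when drawing a random sample of the same size
    from the proteome.
    """
    if N <= 0 or K <= 0 or n <= 0:
        raise ValueError("fold enrichment requires N, K and n all positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    return (k / K) / (n / N)


def hypergeometric_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    The chance that a random size-n sample of the proteome contains at
    least k of the K BPAs; evaluated through log-space mass terms for
    numerical safety at proteome scale.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"infeasible hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} must lie in [0, min(K, n)] = [0, {min(K, n)}]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def screen_proteome(bundle: VaxiJenBundle, proteome: list[ProteinRecord],
                    bpa_ids: Iterable[str], policy: str = "skip-unknown",
                    proteome_name: str = "proteome",
                    on_unknown_bpa: str = "error") -> ProteomeScreenResult:
    """Run the majority-voting predictor over a proteome and score enrichment.

    Every admissible protein is classified; inadmissible proteins (too short
    for the lag, unencodable residues under the chosen policy) are excluded
    from N and logged.  BPA identifiers are matched to proteome identifiers
    after normalizing database prefixes; identifiers matching no proteome
    protein raise an error when ``on_unknown_bpa`` is ``"error"`` and are
    logged and ignored under ``"warn"``.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    if on_unknown_bpa not in ("error", "warn"):
        raise ValueError("on_unknown_bpa must be 'error' or 'warn'")

    results, skipped = predict_batch(bundle, proteome, policy=policy)
    if skipped:
        logger.info("%s: excluded %d inadmissible protein(s) from screening",
                    proteome_name, len(skipped))

    screened_ids = {normalize_protein_id(res.record_id) for res in results}
    bpa_set = {normalize_protein_id(b) for b in bpa_ids}
    proteome_ids = {normalize_protein_id(rec.id) for rec in proteome}
    unknown = bpa_set - proteome_ids
    if unknown:
        message = (f"{proteome_name}: {len(unknown)} BPA id(s) not found in the "
                   f"proteome: {sorted(unknown)[:10]}")
        if on_unknown_bpa == "error":
            raise ValueError(message)
        logger.warning(message)
        bpa_set -= unknown

    bpa_in_scope = bpa_set & screened_ids
    pvc_ids = {normalize_protein_id(res.record_id)
               for res in results if res.verdict == "probable antigen"}

    N = len(results)
    n = len(pvc_ids)
    K = len(bpa_in_scope)
    k = len(bpa_in_scope & pvc_ids)

    return ProteomeScreenResult(
        proteome_name=proteome_name,
        n_proteins=N,
        n_pvc=n,
        pvc_fraction=n / N,
        n_bpa_total=K,
        n_bpa_observed=k,
        bpa_sensitivity=(k / K) if K else 0.0,
        fold_enrichment=fold_enrichment(N, K, n, k) if (K and n) else float("nan"),
        p_value=hypergeometric_pvalue(N, K, n, k) if K else 1.0,
        n_skipped=len(skipped),
    )


_TSV_HEADER = ("proteome", "n_proteins", "n_pvc", "pvc_fraction_pct",
               "n_bpa_total", "n_bpa_observed", "bpa_sensitivity_pct",
               "fold_enrichment", "p_value", "n_skipped")


def screen_result_to_tsv(result: ProteomeScreenResult, header: bool = False) -> str:
    """One TSV row for a screen result (fractions printed as percentages)."""
    row = "\t".join([
        result.proteome_name,
        str(result.n_proteins), str(result.n_pvc),
        f"{100 * result.pvc_fraction:.2f}",
        str(result.n_bpa_total), str(result.n_bpa_observed),
        f"{100 * result.bpa_sensitivity:.2f}",
        f"{result.fold_enrichment:.2f}",
        f"{result.p_value:.3e}",
        str(result.n_skipped),
    ])
    if header:
        return "\t".join(_TSV_HEADER) + "\n" + row
    return row


def combined_summary_tsv(results: list[ProteomeScreenResult]) -> str:
    """Multi-proteome summary table."""
    lines = ["\t".join(_TSV_HEADER)]
    lines += [screen_result_to_tsv(res) for res in results]
    return "\n".join(lines) + "\n"
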