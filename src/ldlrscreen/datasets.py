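"""Built-in example tables.

``reported_funnel_tables`` reconstructs, as synthetic stage tables, the
outcome of the published genome-wide LDLR-activity screen funnel: 21,686
genes screened, 1,491 primary z-rule hits, 250 cherry-picked candidates all
rescreened by deconvolution, of which 160 validated with at least one
individual siRNA — a 64% validation rate. Only the stage counts are
faithful; gene identities, z-values and the up/down split are synthetic
placeholders constructed to satisfy each stage's decision rule, so the
tables exercise the report machinery, not the biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hits

N_GENES_SCREENED = 21686
N_PRIMARY_HITS = 1491
N_CANDIDATES = 250
N_VALIDATED = 160


def reported_funnel_tables(
    z_threshold: float = 2.0,
    deconv_z_threshold: float = 1.6,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(summaries, candidates, deconvolution records) with the published
    stage counts; validation outcomes are derived by running the actual
    deconvolution rule on the constructed siRNA z-vectors."""
    genes = np.array([f"G{i + 1:05d}" for i in range(N_GENES_SCREENED)])
    n_up = N_PRIMARY_HITS // 2 + N_PRIMARY_HITS % 2
    n_down = N_PRIMARY_HITS // 2
    call = np.array(["none"] * N_GENES_SCREENED, dtype=object)
    call[:n_up] = "up"
    call[n_up:n_up + n_down] = "down"

    hit_z = np.where(call == "up", z_threshold + 1.0,
                     np.where(call == "down", -(z_threshold + 1.0), 0.0))
    summaries = pd.DataFrame(
        {
            "gene": genes,
            "replicate_z": [[z, z, 0.0] for z in hit_z],
            "n_replicates_used": 3,
            "mean_z": [np.mean([z, z, 0.0]) for z in hit_z],
            "scorable": True,
            "n_beyond_up": (call == "up").astype(int) * 2,
            "n_beyond_down": (call == "down").astype(int) * 2,
            "hit_call": call,
        }
    )

    # candidates: the first N_CANDIDATES hits carry supporting evidence
    is_hit = call != "none"
    candidate = np.zeros(N_GENES_SCREENED, bool)
    candidate[np.flatnonzero(is_hit)[:N_CANDIDATES]] = True
    candidates = pd.DataFrame(
        {
            "gene": genes,
            "hit_call": call,
            "cholesterol_modulated": candidate,
            "lipid_gwas_flag": False,
            "candidate": candidate,
        }
    )

    cand_idx = np.flatnonzero(candidate)
    sirna_z = []
    for j, i in enumerate(cand_idx):
        sign = 1.0 if call[i] == "up" else -1.0
        if j < N_VALIDATED:  # one siRNA reproduces the phenotype (inclusive)
            sirna_z.append([sign * deconv_z_threshold, 0.0, 0.0])
        else:
            sirna_z.append([0.0, 0.0, 0.0])
    records = pd.DataFrame(
        {
            "gene": genes[cand_idx],
            "primary_direction": call[cand_idx],
            "sirna_z": sirna_z,
        }
    )
    records = hits.validate_deconvolution(records, t=deconv_z_threshold, m=1)
    return summaries, candidates, records
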