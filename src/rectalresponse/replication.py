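"""Optional replication of the published cohort-level numbers.

The cohort-level results quoted below were computed on the real
MSK/TIMING/UM rectal-cancer data (cBioPortal study ``rectal_msk_2022``
plus institutional samples) and cannot be recomputed without that
download.  They are kept here as *replication targets*: given a local
copy of the cBioPortal study export, :func:`replicate_cohort_analysis`
re-runs the pipeline on it.  Without data, the functions refuse to
proceed rather than silently substituting synthetic numbers.
"""

from __future__ import annotations

from pathlib import Path

from . import balance, cohort_io, mutnet, response_model

__all__ = ["REPLICATION_TARGETS", "replicate_cohort_analysis"]

#: published cohort-level values that require the real data to reproduce
REPLICATION_TARGETS = {
    "table1_or_tumor_size": 0.79,
    "table1_or_network_genes": 2.57,
    "table1_or_cooccur_3plus": 8.47,
    "table1_tjur_r2": 0.14,
    "table1_aic": 349.72,
    "cooccurring_pairs_cr": 70,
    "cooccurring_pairs_icr": 38,
    "weighted_tmb_p": 0.0369,
    "tumor_size_p": 0.0069,
    "repair_panel_fraction_cr_pct": 52.0,
    "repair_panel_fraction_icr_pct": 34.0,
}

CBIOPORTAL_STUDY = "rectal_msk_2022"


def replicate_cohort_analysis(data_dir=None, download: bool = False,
                              coding_length_mb: float = 1.5) -> dict:
    """Re-run the cohort analysis on a local cBioPortal study export.

    Parameters
    ----------
    data_dir
        directory holding ``data_mutations.txt`` (MAF) and a clinical
        table ``clinical.tsv`` with canonical columns (see
        :func:`rectalresponse.cohort_io.read_clinical`).
    download
        must be set explicitly to acknowledge that fetching the
        cBioPortal study is a network operation; automatic download is
        not implemented — obtain the study archive manually.
    """
    if data_dir is None:
        if not download:
            raise RuntimeError(
                "replicating the published cohort numbers requires the "
                f"cBioPortal study {CBIOPORTAL_STUDY!r}; pass data_dir= with a "
                "local export, or set download=True to acknowledge the "
                "network requirement")
        raise NotImplementedError(
            f"automatic download is not implemented; fetch the "
            f"{CBIOPORTAL_STUDY!r} archive from cbioportal.org and pass "
            "data_dir=")
    data_dir = Path(data_dir)
    records = cohort_io.read_maf(data_dir / "data_mutations.txt")
    clinical = cohort_io.read_clinical(data_dir / "clinical.tsv")
    kept = cohort_io.filter_variants(records)
    samples = list(clinical["sample_id"])
    matrix = cohort_io.build_mutation_matrix(
        [r for r in kept if r.sample_id in set(samples)], samples)
    tmb = cohort_io.compute_tmb(kept, coding_length_mb, samples)
    group = clinical["response"].to_numpy()

    cohort = balance.iterate_balance(
        clinical, balance.PropensitySpec(
            [c for c in balance.DEFAULT_COVARIATES if c in clinical.columns]))
    idx = cohort.matching_weights.index
    balanced_samples = clinical.loc[idx, "sample_id"]
    tmb_test = balance.compare_tmb_weighted(
        tmb.loc[balanced_samples].to_numpy(),
        clinical.loc[idx, "response"].to_numpy(),
        cohort.matching_weights.to_numpy())

    out = {"weighted_tmb_p": tmb_test.p_value,
           "balance_converged": cohort.report.converged}
    for label, grp_label in (("cr", "CR"), ("icr", "ICR")):
        sub = matrix.subset_samples(group == grp_label)
        genes = mutnet.select_candidate_genes(sub)
        if len(genes) >= 2:
            inter = mutnet.pairwise_interactions(sub, genes)
            out[f"cooccurring_pairs_{label}"] = mutnet.count_significant_pairs(
                inter, "co-occurring")
    frac_cr, frac_icr, chi = mutnet.repair_panel_fraction(matrix, group)
    out["repair_panel_fraction_cr_pct"] = 100 * frac_cr
    out["repair_panel_fraction_icr_pct"] = 100 * frac_icr
    if chi is not None:
        out["repair_panel_p"] = chi.p_value

    genes = mutnet.select_candidate_genes(matrix)
    inter = [it for it in mutnet.pairwise_interactions(matrix, genes)
             if it.label == "co-occurring"]
    screening = response_model.screen_predictors(matrix, inter, group)
    feats = response_model.build_features(clinical, matrix, screening)
    model = response_model.run_model_selection(feats)
    out["table1_tjur_r2"] = model.tjur_r2
    out["table1_aic"] = model.aic
    for term, key in (("tumor_size", "table1_or_tumor_size"),
                      ("network_gene_mutated", "table1_or_network_genes"),
                      ("cooccur_3plus", "table1_or_cooccur_3plus")):
        if term in model.odds_ratios.index:
            out[key] = float(model.odds_ratios.loc[term, "OR"])
    return out
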