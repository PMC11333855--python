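"""End-to-end pipeline: bundle directory in, result TSVs out.

Stages: MAG quality filtering -> consensus annotation -> capability matrix
-> CGC detection and substrate inference -> per-MAG/per-class statistics ->
co-abundance grouping -> expression summaries.  Analysis is seed-free and
deterministic: re-running on identical inputs and config yields
byte-identical primary TSV outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import cgc as cgc_mod
from . import coabundance as co
from . import expression as expr_mod
from . import profiles as prof
from .config import PipelineConfig
from .consensus import annotate_proteins, filter_mags
from .synthetic import read_bundle


def run_pipeline(
    config: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path,
) -> dict:
    """Run every stage on a bundle directory; returns in-memory results.

    Writes consensus calls, sulfatase calls, capability matrix, CGC table,
    taxon CGC summaries, MAG profiles, density tests, Bray-Curtis matrix,
    genus section summaries, correlation/groups/fold-change tables, pooled
    enzyme counts, expression summaries, and a run log echoing the config.
    Partial outputs are removed on failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        written.append(path)

    try:
        bundle = read_bundle(input_dir)
        catalog = cat.load_catalog()

        retained = filter_mags(
            bundle["mag_metadata"], config.min_completeness, config.max_contamination
        )
        retained_ids = [m.mag_id for m in retained]
        genes = [g for g in bundle["genes"] if g.mag_id in set(retained_ids)]
        protein_to_mag = {g.gene_id: g.mag_id for g in genes}
        hits = [h for h in bundle["hits"] if h.protein_id in protein_to_mag]

        calls, sulf_calls = annotate_proteins(hits, protein_to_mag, config)

        # mannitol genotypes from curated gene symbols (product labels)
        genotypes = []
        for mag in retained_ids:
            symbols = {
                g.product_label
                for g in genes
                if g.mag_id == mag and g.product_label in
                ("m2dh", "fructokinase", "pts_mannitol", "m1pdh")
            }
            genotypes.append(cat.call_mannitol_routes(mag, symbols))

        matrix, support = cat.build_capability_matrix(
            calls, sulf_calls, genotypes, retained_ids, catalog
        )

        # CGC detection: CAZyme role iff an accepted consensus call exists
        families = dict(zip(calls["protein_id"], calls["family"]))
        roles = {}
        for g in genes:
            if g.gene_id in families:
                roles[g.gene_id] = "CAZyme"
            else:
                r = bundle["roles"].get(g.gene_id, "other")
                roles[g.gene_id] = r if r in ("TC", "TF", "STP") else "other"
        clusters = cgc_mod.analyze_clusters(genes, roles, families, catalog, config)
        class_summary = cgc_mod.summarize_cgcs_by_taxon(clusters, retained, "class")
        genus_summary = cgc_mod.summarize_cgcs_by_taxon(clusters, retained, "genus")

        profiles = prof.build_profiles(retained, calls, config)
        prof_df = prof.profiles_to_frame(profiles)
        classes = sorted(
            c for c in prof_df["class"].unique()
            if (prof_df["class"] == c).sum() >= 2
        )
        test_rows = []
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                w, p = prof.compare_density_classes(profiles, a, b)
                test_rows.append({"class_a": a, "class_b": b, "ranksum_w": w, "p": p})
        density_tests = pd.DataFrame(
            test_rows, columns=["class_a", "class_b", "ranksum_w", "p"]
        )
        bc = prof.bray_curtis_matrix(profiles)
        weight_counts = cat.count_weight_classes(calls, catalog)

        meta_samples = [s for s in bundle["samples"] if s.assay == "metagenome"]
        genus_sections = prof.genus_section_summary(
            bundle["abundance"], meta_samples, retained, "genus"
        )

        abundance = bundle["abundance"][
            [m for m in bundle["abundance"].columns if m in set(retained_ids)]
        ]
        corr = co.correlate(abundance)
        fcs = co.section_fold_change(abundance, meta_samples, config.fc_pseudocount)
        groups = co.delineate_groups(
            corr,
            alpha=config.corr_alpha,
            min_r=config.corr_min_r,
            cut_height=config.group_cut_height,
            abundance=abundance,
            samples=meta_samples,
        )
        panel = co.group_capability_panel(groups, calls, catalog)
        pooled = prof.pool_enzyme_counts(
            calls, {g.group_id: g.members for g in groups}, retained, catalog
        )

        expr_summary = expr_mod.relative_expression_by_class(
            bundle["expression"], calls, sulf_calls, clusters,
            retained, bundle["samples"],
        )
        mt_sections = sorted(
            {s.section for s in bundle["samples"] if s.assay == "metatranscriptome"}
        )
        top_rows = []
        for sec in mt_sections:
            for c in expr_mod.top_cgc_by_expression(
                bundle["expression"], clusters, bundle["samples"], sec,
                config.expression_quantile,
            ):
                top_rows.append(
                    {
                        "section": sec,
                        "cgc_id": c.cgc_id,
                        "mag_id": c.mag_id,
                        "substrates": ",".join(sorted(c.substrates)),
                        "expression_share": c.expression_share,
                    }
                )
        top_cgcs = pd.DataFrame(
            top_rows,
            columns=["section", "cgc_id", "mag_id", "substrates", "expression_share"],
        )

        # ---- write outputs
        save(calls, "consensus_calls.tsv")
        save(sulf_calls, "sulfatase_calls.tsv")
        save(matrix.astype(int), "capability_matrix.tsv", index=True)
        save(cgc_mod.clusters_to_frame(clusters), "cgc_table.tsv")
        save(class_summary, "cgc_class_summary.tsv")
        save(genus_summary, "cgc_genus_summary.tsv")
        save(prof_df, "mag_profiles.tsv")
        save(density_tests, "density_tests.tsv")
        save(bc, "bray_curtis.tsv", index=True)
        save(genus_sections, "genus_section_summary.tsv")
        save(co.correlation_to_frame(corr), "correlations.tsv")
        save(co.groups_to_frame(groups), "coabundance_groups.tsv")
        save(
            pd.DataFrame(
                [
                    {
                        "mag_id": f.mag_id,
                        "mean_iv": f.mean_iv,
                        "mean_v": f.mean_v,
                        "log10_fc": f.log10_fc,
                    }
                    for f in fcs
                ],
                columns=["mag_id", "mean_iv", "mean_v", "log10_fc"],
            ),
            "fold_changes.tsv",
        )
        save(panel, "group_capability_panel.tsv")
        save(pooled, "pooled_enzyme_counts.tsv")
        save(expr_summary, "expression_summary.tsv")
        save(top_cgcs, "top_cgcs_by_expression.tsv")
        save(
            pd.DataFrame(
                [
                    {"weight_class": wc, "gene_count": gc, "mag_count": mc}
                    for wc, (gc, mc) in sorted(weight_counts.items())
                ],
                columns=["weight_class", "gene_count", "mag_count"],
            ),
            "weight_class_counts.tsv",
        )
        log_path = out / "run_log.txt"
        with open(log_path, "w") as fh:
            fh.write("cazpipe run\nconfig:\n")
            for k, v in sorted(config.as_dict().items()):
                fh.write(f"  {k}: {v}\n")
            fh.write(f"retained_mags: {len(retained_ids)}\n")
            fh.write(f"consensus_calls: {len(calls)}\n")
            fh.write(f"clusters: {len(clusters)}\n")
        written.append(log_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return {
        "retained": retained,
        "calls": calls,
        "sulfatase_calls": sulf_calls,
        "capability": matrix,
        "capability_support": support,
        "clusters": clusters,
        "class_summary": class_summary,
        "genus_summary": genus_summary,
        "profiles": profiles,
        "density_tests": density_tests,
        "bray_curtis": bc,
        "weight_class_counts": weight_counts,
        "genus_sections": genus_sections,
        "correlation": corr,
        "groups": groups,
        "fold_changes": fcs,
        "group_panel": panel,
        "pooled_counts": pooled,
        "expression_summary": expr_summary,
        "top_cgcs": top_cgcs,
    }
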