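"""Gene/QTL annotation and term enrichment of called PSRs.

Genes attach to regions on any overlap; QTL intervals are first cleaned
(drop > 1 Mb, merge pairs overlapping > 50% of the shorter) and then
matched by strict containment. Term enrichment is an upper-tail
hypergeometric test at raw p < 0.05.
"""

import tempfile

import sweepscan as sw

cfg = sw.SyntheticConfig(seed=5, sweep=sw.SweepConfig())
sim = sw.simulate_two_populations(cfg)
track = sw.xpehh_scan(sim.panels["WHITE"], sim.panels["GREEN"])
sw.normalize_scores(track)
sw.scores_to_pvalues(track)
psrs = sw.call_psrs(track, chrom_sizes=cfg.chrom_sizes())
print(f"{len(psrs.regions)} PSRs called")

with tempfile.TemporaryDirectory() as tmp:
    paths = sw.make_annotation_fixture(cfg, tmp, seed=5)
    genes = sw.read_genes(paths["genes"])
    raw_qtls = sw.read_qtl_table(paths["qtl"])
    term_map = sw.read_term_map(paths["terms"])

qtls = sw.prepare_qtl(raw_qtls)
print(f"QTL cleaning: {len(raw_qtls)} -> {len(qtls)} "
      "(dropped the planted >1 Mb interval, merged the >50% overlap pair)")

hits = sw.genes_in_regions(psrs, genes)
selected = {g.gene_id for gs in hits.values() for g in gs}
print(f"{len(selected)} genes overlap a PSR")

report = sw.qtl_overlap(psrs, qtls)
print(f"{report.n_psr_with_overlap} PSRs contain or sit inside a QTL; "
      f"per trait class: {report.class_counts}")

if selected:
    background = {g.gene_id for g in genes}
    results = sw.enrichment_test(selected, background, term_map, alpha=0.05)
    top = results[0]
    print(f"most enriched term: {top.term_id} "
          f"(k={top.k}/{top.n} selected vs K={top.K}/{top.N} background, "
          f"p={top.p:.3g}{', significant' if top.significant else ''})")
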