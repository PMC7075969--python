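"""Build a disease signature from a differential-expression table and map
it onto a probe namespace.

A disease signature is the pair of significantly up- and down-regulated
gene sets of a condition versus its control.  Before it can be queried
against a perturbation database the gene symbols must be translated into
the database's probe identifiers through an offline lookup table — genes
without a probe are dropped, and a probe reachable from both sides is
discarded as a conflict.
"""

import sigconn as sc

# A miniature DE table: (gene, log2 fold change, q-value).
records = [
    sc.DifferentialExpressionRecord(g, fc, q)
    for g, fc, q in [
        ("Pik3cb", +1.8, 0.004),
        ("Camk2a", -2.1, 0.001),
        ("Grin2b", +0.9, 0.030),
        ("Fmr1",   -3.5, 0.0001),
        ("Actb",   +0.1, 0.900),   # not significant
        ("Mtor",   +0.6, 0.048),
        ("Dlg4",   -0.7, 0.020),
    ]
]

signature = sc.build_disease_signature(records, q_threshold=0.05)
print(f"up-regulated genes  : {signature.up_tags}")
print(f"down-regulated genes: {signature.down_tags}")

# Mouse symbol -> human array probe lookup (many-to-many), case-folded.
probe_map = sc.ProbeMap(
    [
        ("PIK3CB", "201723_s_at"), ("PIK3CB", "212688_at"),
        ("CAMK2A", "213108_at"), ("GRIN2B", "210412_at"),
        ("FMR1", "203689_s_at"), ("MTOR", "202288_at"),
        # Dlg4 intentionally missing from the table
    ]
)
mapped = sc.map_to_probes(signature, probe_map, case_fold=True)
print(f"\nprobe signature up  : {mapped.up_tags}")
print(f"probe signature down: {mapped.down_tags}")
print(
    f"dropped {mapped.provenance['n_dropped']} unmapped gene(s): "
    f"{mapped.provenance['dropped_genes']}"
)
# The counts matter: cross-species signatures never map completely, and the
# audit trail in `provenance` records exactly what was lost.
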