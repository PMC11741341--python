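"""qPCR quantification formulas: ΔΔCt relative expression and ChIP fold enrichment."""

from secretomics import ChipCtRecord, CtRecord, chip_fold_enrichment, ddct, mean_ct_record

# Relative expression of a gene in tumor vs control gut, normalized to RP49.
tumor = mean_ct_record([
    CtRecord("tumor", "Pvf1", "RP49", 20.1, 15.0),
    CtRecord("tumor", "Pvf1", "RP49", 19.9, 15.1),
    CtRecord("tumor", "Pvf1", "RP49", 20.0, 14.9),
])
control = mean_ct_record([
    CtRecord("ctrl", "Pvf1", "RP49", 24.0, 16.0),
    CtRecord("ctrl", "Pvf1", "RP49", 23.9, 15.9),
    CtRecord("ctrl", "Pvf1", "RP49", 24.1, 16.1),
])
fold = ddct(tumor, control)
print(f"Pvf1 relative expression (tumor/control): {fold:.2f}-fold")
# dCt(tumor) = 5.0, dCt(ctrl) = 8.0: ddCt = -3 means the target reaches
# threshold 3 normalized cycles earlier, i.e. 2^3 = 8x more transcript.

# ChIP-qPCR: enrichment of a regulatory region in the tagged IP vs the
# non-tagged control IP.
region = ChipCtRecord("Pvf1_promoter", ct_ip=22.0, ct_control=25.0)
print(f"ChIP fold enrichment at {region.region}: {chip_fold_enrichment(region):.1f}x")
# Ct(IP) three cycles earlier than control: 2^3 = 8-fold enrichment.
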