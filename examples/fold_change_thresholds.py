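"""The variance-adaptive fold-change threshold and logFC/fold conversion.

The significance threshold adapts to the spread of the data:
log2(FCT) = 1.47 x median per-feature SD.  The published protein matrix had
median SD 0.4375, giving FCT = 1.6; a peptide matrix with median SD ~ 0.577
gives FCT = 1.8.  Fold enrichments are 2^|logFC|.
"""

from tmtserum import fct_from_median_sd, logfc_to_fold

for level, sd in [("protein", 0.4375), ("peptide", 0.5769)]:
    fct = fct_from_median_sd(sd, 1.47)
    print(f"{level}: median SD {sd} -> FCT = 2^(1.47 x {sd}) "
          f"= {fct:.3f} (applied as {round(fct, 1)})")

print("\nfold enrichment from reported log2 fold changes:")
for gene, logfc in [("ARHGAP35", -1.58), ("CALU", -1.047),
                    ("SERPINE1", -1.144), ("AGER", 0.968)]:
    side = "NR" if logfc > 0 else "SR"
    print(f"  {gene:10s} logFC {logfc:+.3f} -> {logfc_to_fold(logfc):.2f}-fold "
          f"enriched in {side}")
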