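# Maps GFF3 gene_biotype values (NCBI dialect) onto the closed gene-type
# vocabulary {mRNA, ncRNA, pseudogene, other}. Editable: add rows as needed;
# biotypes absent from this table fall through to "other".
# Columns: gene_biotype <TAB> gene_type
protein_coding	mRNA
mRNA	mRNA
lncRNA	ncRNA
lnc_RNA	ncRNA
ncRNA	ncRNA
antisense_RNA	ncRNA
miRNA	ncRNA
snoRNA	ncRNA
snRNA	ncRNA
scRNA	ncRNA
scaRNA	ncRNA
rRNA	ncRNA
tRNA	ncRNA
misc_RNA	ncRNA
vault_RNA	ncRNA
Y_RNA	ncRNA
RNase_P_RNA	ncRNA
RNase_MRP_RNA	ncRNA
telomerase_RNA	ncRNA
guide_RNA	ncRNA
antisense	ncRNA
pseudogene	pseudogene
processed_pseudogene	pseudogene
unprocessed_pseudogene	pseudogene
transcribed_pseudogene	pseudogene
polymorphic_pseudogene	pseudogene
rRNA_pseudogene	pseudogene
tRNA_pseudogene	pseudogene
IG_pseudogene	pseudogene
TR_pseudogene	pseudogene
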