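# Synthetic offline snapshot of gene -> free-text descriptions used by the
# disease-term filter. Columns: gene, description.
gene	description
APC	APC regulator of WNT signaling pathway; familial adenomatous polyposis, autosomal dominant predisposition to colorectal cancer
BRCA1	BRCA1 DNA repair associated; hereditary breast and ovarian cancer, autosomal dominant
BRCA2	BRCA2 DNA repair associated; hereditary breast and ovarian cancer, autosomal dominant
CFTR	CF transmembrane conductance regulator; cystic fibrosis, autosomal recessive
DMD	dystrophin; Duchenne muscular dystrophy, X-linked recessive
FBN1	fibrillin 1; Marfan syndrome, autosomal dominant connective tissue disorder
KCNQ1	potassium voltage-gated channel subfamily Q member 1; long QT syndrome, autosomal dominant
LDLR	low density lipoprotein receptor; familial hypercholesterolemia, autosomal dominant
MLH1	mutL homolog 1; Lynch syndrome, autosomal dominant predisposition to colorectal cancer
MSH2	mutS homolog 2; Lynch syndrome, autosomal dominant predisposition to colorectal cancer
MYH7	myosin heavy chain 7; hypertrophic cardiomyopathy, autosomal dominant
PTEN	phosphatase and tensin homolog; PTEN hamartoma tumor syndrome, autosomal dominant
SCN1A	sodium voltage-gated channel alpha subunit 1; Dravet syndrome, autosomal dominant epileptic encephalopathy
TP53	tumor protein p53; Li-Fraumeni syndrome, autosomal dominant cancer predisposition
TTN	titin; titinopathies including dilated cardiomyopathy, autosomal dominant and recessive forms
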