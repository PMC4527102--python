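"""Bundled reference data for validation.

A published two-group comparison of synovial-tissue proteomes (rheumatoid
arthritis, 15 case samples, versus osteoarthritis, 5 control samples;
triplicate injections pooled before testing) reported, for its 31
strongest differential proteins, the per-group detection counts, pooled
spectral counts, G-test p-value, spectral index and log2 spectral-count
ratio.  Those printed values are reproduced here verbatim as a validation
fixture: the detection and pooled counts are sufficient to recompute the
spectral index exactly, and the printed p and R_SC values exercise the
top-tier classification rule.

The printed G-test p-values and R_SC values are *not* recomputable from
this table alone: both depend on the group count totals over the full
identified proteome, which was not published per sample.
"""

from __future__ import annotations

import io

import pandas as pd

from .count_data import ProteinGroupSummary

#: biological sample sizes of the reference comparison
REF_N_CONTROL = 5
REF_N_CASE = 15

# columns: d_a/n_a = control (OA) detection/pooled counts, d_b/n_b = case
# (RA); p_g, spi, rsc as printed.
_REFERENCE_TSV = """\
entry_name	gene_id	description	length_aa	d_a	d_b	n_a	n_b	p_g	spi	rsc
A33	HLA-A	HLA class I histocompatibility antigen, A-33 alpha chain	365	1	12	2	84	7.667E-08	0.777	2.904
TXND5	TXNDC5	Thioredoxin domain-containing protein 5	432	2	12	4	87	1.929E-06	0.747	2.261
DEF1	DEFA1	Neutrophil defensin 1	94	0	11	0	78	4.879E-10	0.733	4.177
RL7A	RPL7A	60S ribosomal protein L7a	266	0	10	0	37	2.032E-05	0.667	3.125
TPM3	TPM3	Tropomyosin alpha-3 chain	284	1	10	5	102	4.128E-07	0.626	2.237
S10A8	S100A8	Protein S100-A8	93	0	9	0	85	8.08E-11	0.600	4.299
VINC	VCL	Vinculin	1134	1	9	3	70	1.372E-05	0.567	2.257
S10A9	S100A9	Protein S100-A9	114	0	8	0	109	1.732E-13	0.533	4.654
EZRI	EZR	Ezrin	586	0	8	0	69	4.951E-09	0.533	4.003
FRIH	FTH1	Ferritin heavy chain	183	0	8	0	40	9.239E-06	0.533	3.234
K2C6A	KRT6A	Keratin, type II cytoskeletal 6A	564	0	7	0	156	1.084E-18	0.467	5.168
PERP1	PACAP	Plasma cell-induced resident endoplasmic reticulum protein	189	0	6	0	43	4.21E-06	0.400	3.335
PERM	MPO	Myeloperoxidase	745	0	5	0	65	1.39E-08	0.333	3.918
1C12	HLA-C	HLA class I histocompatibility antigen, Cw-12 alpha chain	366	0	5	0	46	1.922E-06	0.333	3.430
K2C5	KRT5	Keratin, type II cytoskeletal 5	590	0	4	0	93	1.039E-11	0.267	4.427
TRFL	LTF	Lactotransferrin	710	0	3	0	98	2.886E-12	0.200	4.502
K1C14	KRT14	Keratin, type I cytoskeletal 14	472	0	3	0	81	2.257E-10	0.200	4.231
ACTN1	ACTN1	Alpha-actinin-1	892	0	3	0	47	1.481E-06	0.200	3.460
K2C6C	KRT6C	Keratin, type II cytoskeletal 6C	564	0	1	0	64	1.799E-08	0.067	3.896
POSTN	POSTN	Periostin	836	2	5	17	13	5.517E-05	-0.082	-2.170
CBPQ	CPQ	Plasma glutamate carboxypeptidase	472	1	0	6	0	6.486E-05	-0.200	-4.349
AEBP1	AEBP1	Adipocyte enhancer-binding protein 1	1158	1	0	6	0	6.486E-05	-0.200	-4.349
COFA1	COL15A1	Collagen alpha-1 (XV) chain	1388	1	0	7	0	1.354E-05	-0.200	-4.535
MYH11	MYH11	Myosin-11	1972	1	0	10	0	1.273E-07	-0.200	-4.983
HBG2	HBG2	Hemoglobin subunit gamma-2	147	1	0	25	0	1.278E-17	-0.200	-6.207
ASPN	ASPN	Asporin	380	2	2	24	12	1.693E-08	-0.222	-2.744
HBD	HBD	Hemoglobin subunit delta	147	4	5	245	216	9.342E-48	-0.269	-2.012
CO4A	C4A	Complement C4-A	1744	2	1	13	4	3.329E-06	-0.290	-3.254
COCA1	COL12A1	Collagen alpha-1 (XII) chain	3063	2	1	17	5	6.862E-08	-0.294	-3.359
COEA1	COL14A1	Collagen alpha-1 (XIV) chain	1796	4	6	167	108	4.41E-43	-0.329	-2.449
FMOD	FMOD	Fibromodulin	376	2	0	8	0	2.845E-06	-0.400	-4.700
"""


def reference_table() -> pd.DataFrame:
    """The 31-protein reference table as a DataFrame (printed values)."""
    return pd.read_csv(io.StringIO(_REFERENCE_TSV), sep="\t")


def reference_summaries() -> list[ProteinGroupSummary]:
    """Group summaries rebuilt from the reference table's printed counts.

    Group totals are the column sums over these 31 rows; they differ from
    the unpublished full-proteome totals, so statistics that depend on
    them (R_SC, G-test) will not match the printed values — the spectral
    index, which ignores totals, will.
    """
    df = reference_table()
    t_a, t_b = int(df.n_a.sum()), int(df.n_b.sum())
    return [
        ProteinGroupSummary(
            entry_name=row.entry_name,
            n_a=int(row.n_a),
            n_b=int(row.n_b),
            d_a=int(row.d_a),
            d_b=int(row.d_b),
            t_a=t_a,
            t_b=t_b,
            cap_n_a=REF_N_CONTROL,
            cap_n_b=REF_N_CASE,
        )
        for row in df.itertuples(index=False)
    ]
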