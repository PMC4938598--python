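"""Worked-example breakpoint-region catalogs from a published genome-wide
survey of eight human tumor entities.

The survey segmented SNP-array log2-ratio profiles of 2,737 tumor samples
(377 breast, 189 colorectal, 340 gastric, 291 lung, 1,104 pediatric
medulloblastoma, 207 ovarian, 120 prostate, 109 renal) and 432 normal
samples, and counted recurrent breakpoint regions (BPRs) per cohort.  Two of
its printed summary tables are transcribed here as plain data:

* ``bpr_count_table`` — the 47 BPRs detected in over 2% of all sample sets,
  with absolute carrier counts per cohort, the cancer total and the normal
  count.
* ``nof_frequency_table`` — the 32 noticeable-occurrence-frequency BPRs
  (>= 10% of samples in at least one tumor entity and/or the normal group),
  with percent frequencies per cohort and the printed recurrency class.

These tables serve as exact worked examples for the frequency, NOF and
classification arithmetic; they are inputs, not results, of this package.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

ENTITIES = ["breast", "colorectal", "gastric", "lung",
            "medulloblastoma", "ovarian", "prostate", "renal"]

GROUP_SIZES = {
    "breast": 377,
    "colorectal": 189,
    "gastric": 340,
    "lung": 291,
    "medulloblastoma": 1104,
    "ovarian": 207,
    "prostate": 120,
    "renal": 109,
}

NORMAL_GROUP = "normal"
NORMAL_SIZE = 432

# 47 BPRs found in over 2% of all sample sets: absolute carrier counts.
_COUNTS_TSV = """\
chrom	start	end	breast	colorectal	gastric	lung	medulloblastoma	ovarian	prostate	renal	cancer	normal
1	148916177	149040066	11	5	9	9	23	4	1	0	62	5
2	172338300	172339964	30	27	1	5	25	17	0	8	113	3
2	172345151	172348021	17	27	0	4	18	16	0	8	90	3
2	242718444	242725752	7	8	3	2	51	1	1	7	80	6
4	9994215	9996852	47	0	5	4	0	0	0	4	60	0
4	9997801	10001833	52	0	25	10	0	0	0	4	91	0
4	70950894	70951184	8	12	0	0	96	0	0	5	121	0
4	70951806	70953579	8	12	0	0	96	0	0	5	121	0
5	4443854	4445976	1	0	63	6	0	0	0	0	70	4
6	29850274	29871636	8	3	20	10	31	14	4	2	92	15
6	29899493	29899677	2	1	11	3	29	8	3	0	57	9
6	67048629	67049406	9	24	9	8	13	1	0	5	69	2
6	77422497	77439868	27	19	8	15	67	10	2	6	154	14
6	77452270	77452804	15	15	7	11	26	5	0	1	80	6
6	77452804	77461073	12	4	1	4	41	5	1	5	73	8
6	78962626	78979398	20	15	12	7	108	8	1	5	176	12
6	79026686	79039234	15	15	7	5	104	8	0	4	158	11
8	5594132	5601352	8	6	7	4	29	5	2	2	63	6
8	6104977	6107427	6	30	4	3	15	11	0	9	78	1
8	39225941	39288762	29	23	16	24	97	9	1	10	209	24
8	39397732	39398022	28	21	16	24	97	10	1	10	207	22
8	43778914	46924211	34	7	9	21	7	17	17	6	118	13
8	137677896	137681619	8	5	2	6	29	3	2	4	59	10
11	9241448	9250359	4	2	1	5	32	2	0	12	58	4
11	86410303	86410905	7	13	1	1	56	4	0	3	85	1
11	86412698	86412880	7	13	10	3	59	3	0	3	98	1
12	33299791	33302438	11	7	4	10	32	5	1	2	72	10
12	33303866	33312197	24	7	3	10	43	5	1	3	96	11
14	41606882	41606899	2	7	4	2	50	0	0	3	68	5
14	41653977	41670102	2	7	4	2	50	0	0	3	68	6
16	70842097	70854381	58	0	1	3	20	1	0	0	83	1
16	71202489	71207879	30	0	2	3	19	8	0	0	62	0
16	85082710	85091864	1	9	1	1	172	3	0	11	198	1
16	85091864	85092483	42	43	32	76	308	44	0	12	557	21
16	85092748	85092892	37	52	33	74	480	47	0	23	746	22
17	18917513	18917915	7	3	1	2	111	0	0	0	124	0
17	18917915	19168912	2	1	0	0	170	0	0	0	173	0
17	44162597	44165803	12	7	4	3	50	2	3	8	89	5
17	44572303	44789285	17	12	4	6	61	4	4	7	115	5
17	54158456	54163047	10	0	5	0	40	1	1	2	59	6
17	54172591	54173463	11	0	10	3	33	5	1	1	64	3
18	4976160	4979612	1	31	14	0	15	0	0	28	89	51
18	4989683	4990804	1	22	8	0	23	0	3	22	79	49
21	20346687	20347871	4	12	0	0	43	0	0	7	66	0
21	20353826	20353905	4	13	2	0	43	0	0	6	68	0
21	23655764	23655900	0	1	34	35	7	11	4	0	92	29
21	23664658	23667121	2	5	39	39	40	24	9	1	159	39
"""

# 32 NOF-BPRs: percent frequencies per cohort and the published class label
# (1 = entity-specific, 2 = cancer-specific, 3 = common).
_NOF_TSV = """\
chrom	start	end	breast	colorectal	gastric	lung	medulloblastoma	ovarian	prostate	renal	normal	bpr_class
2	172338300	172339964	7.96	14.29	0.29	1.72	2.26	8.21	0.00	7.34	0.69	3
2	172345151	172348021	4.51	14.29	0.00	1.37	1.63	7.73	0.00	7.34	0.69	3
4	3027493	3027897	0.00	0.00	11.47	0.00	0.00	0.00	0.00	1.83	1.39	3
4	3029623	3035631	0.00	0.00	11.76	0.00	0.00	0.00	0.00	1.83	1.16	3
4	9994215	9996852	12.47	0.00	1.47	1.37	0.00	0.00	0.00	3.67	0.00	2
4	9997801	10001833	13.79	0.00	7.35	3.44	0.00	0.00	0.00	3.67	0.00	2
5	4430296	4431868	0.27	0.00	11.18	0.69	0.00	0.00	0.00	0.00	1.16	1
5	4443854	4445976	0.27	0.00	18.53	2.06	0.00	0.00	0.00	0.00	0.93	3
5	61569169	61572989	0.00	0.00	0.00	0.34	1.09	0.00	0.00	12.84	0.46	2
5	126152745	126158200	0.27	0.00	0.00	1.37	1.54	0.00	0.00	10.09	1.16	3
6	67048629	67049406	2.39	12.70	2.65	2.75	1.18	0.48	0.00	4.59	0.46	2
6	77422497	77439868	7.16	10.05	2.35	5.15	6.07	4.83	1.67	5.50	3.24	3
7	35396655	35397567	0.00	0.00	1.03	3.82	0.27	11.59	5.83	0.00	8.33	3
8	6104977	6107427	1.59	15.87	1.18	1.03	1.36	5.31	0.00	8.26	0.23	2
8	39225941	39288762	7.69	12.17	4.71	8.25	8.79	4.35	0.83	9.17	5.56	3
8	39397732	39398022	7.43	11.11	4.71	8.25	8.79	4.83	0.83	9.17	5.09	3
8	43778914	46924211	9.02	3.70	2.65	7.22	0.63	8.21	14.17	5.50	3.01	3
9	9337599	9338146	0.27	0.53	13.53	0.34	0.00	0.00	0.00	0.00	0.46	1
9	9338417	9339871	0.27	0.53	11.76	0.69	0.00	0.00	0.00	0.00	0.46	1
10	44051819	44065519	0.53	0.00	0.00	1.03	0.36	0.00	0.00	10.09	0.23	2
11	9241448	9250359	1.06	1.06	0.29	1.72	2.90	0.97	0.00	11.01	0.93	3
14	35070371	35076347	0.00	0.00	0.00	0.34	0.45	0.00	0.00	10.09	0.46	1
16	70842097	70854381	15.38	0.00	0.29	1.03	1.81	0.48	0.00	0.00	0.23	2
16	85082710	85091864	0.27	4.76	0.29	0.34	15.58	1.45	0.00	10.09	0.23	2
16	85091864	85092483	11.14	22.75	9.41	26.12	27.90	21.26	0.00	11.01	4.86	3
16	85092748	85092892	9.81	27.51	9.71	25.43	43.48	22.71	0.00	21.10	5.09	3
17	18917513	18917915	1.86	1.59	0.29	0.69	10.05	0.00	0.00	0.00	0.00	2
17	18917915	19168912	0.53	0.53	0.00	0.00	15.40	0.00	0.00	0.00	0.00	1
18	4976160	4979612	0.27	16.40	4.12	0.00	1.36	0.00	0.00	25.69	11.81	3
18	4989683	4990804	0.27	11.64	2.35	0.00	2.08	0.00	2.50	20.18	11.34	3
21	23655764	23655900	0.00	0.53	10.00	12.03	0.63	5.31	3.33	0.00	6.71	3
21	23664658	23667121	0.53	2.65	11.47	13.40	3.62	11.59	7.50	0.92	9.03	3
"""


def bpr_count_table() -> pd.DataFrame:
    """Published carrier counts of the 47 BPRs seen in over 2% of samples."""
    return pd.read_csv(StringIO(_COUNTS_TSV), sep="\t")


def nof_frequency_table() -> pd.DataFrame:
    """Published percent frequencies and classes of the 32 NOF-BPRs."""
    return pd.read_csv(StringIO(_NOF_TSV), sep="\t")
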