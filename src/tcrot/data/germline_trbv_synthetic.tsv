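v_allele	cdr1	cdr2	cdr2_5	species
TRBV2*01	CMMGS-C	DHVWFVVS	YRLRTQ	human
TRBV3-1*01	HPRITFM	CDEMLDNW	VPSQEI	human
TRBV4-1*01	KMEIFKM	TYSRHRFY	WKPLLV	human
TRBV4-2*01	QFFRWNI	CQCPFYDQ	MSIWFE	human
TRBV5-1*01	AQISNVC	S-WENDPR	GMMEPM	human
TRBV6-1*01	KGAPWWK	HLRPVTIP	EDFTNK	human
TRBV6-5*01	D-LFEIV	V-WAGCRH	IVYCFH	human
TRBV6-5*02	GPNNHFP	CYKCQVLA	FEELYE	human
TRBV7-2*01	IMNVGCD	NVRYPT-M	IKWNFD	human
TRBV7-9*01	IADHYKL	RGILHMRN	QIEDYY	human
TRBV9*01	P-EHEHA	PIIFDNIL	PGTDNK	human
TRBV10-3*01	PSTYVWQ	CKYP-YWY	HTHHTP	human
TRBV11-2*01	EGCCESI	YRYN-VLW	QMRYVI	human
TRBV12-3*01	KFMADWA	GAFKNRDP	KIWYCD	human
TRBV13*01	KLHGMWV	RQHIQYAD	GCEWFS	human
TRBV13*02	HAQSMAQ	VWCH-IEK	FFAMAG	human
TRBV14*01	FIKVCTW	YRGNGEPT	FNTNWF	human
TRBV15*01	TTMWGEV	AKDITSKS	FTVVFQ	human
TRBV16*01	TWQILFM	AYCPMQFN	CQNDSS	human
TRBV18*01	EGQDNKC	QI-WMQHS	AGVHVV	human
TRBV19*01	DAHKKNW	W-AFRGGS	HTRNYT	human
TRBV20-1*01	FAHEDET	EANS-RLF	TWVTFS	human
TRBV24-1*01	HQYYNVC	YFKSLIAT	DPHIGD	human
TRBV25-1*01	GLAY-NQ	WGFYDGFN	ETVQDP	human
TRBV25-1*02	PDQSLMD	TATKAAPS	AFVCRA	human
TRBV27*01	LQYLP-V	IKDNYPFF	PGCHTR	human
TRBV28*01	PEGDWNV	QIGVPTCI	MGRHSH	human
TRBV29-1*01	MGDVI-Y	NLH-WMSE	KSAAGQ	human
TRBV29-1*02	QPLNAVL	GIYLAAYE	HISMMC	human
TRBV30*01	RYVGKDY	EWVEHH-W	QAELWY	human
TRBV30*02	IMIGNYQ	WKDKLMKS	LIYVVC	human
TRBV1*01	VCFFFAK	KHYLEA-N	SWVYKI	mouse
TRBV3*01	QFD-WAF	HELSA-SS	NWNCGW	mouse
TRBV4*01	AEKAMMT	CREYPWNY	AQNEIN	mouse
TRBV5*01	DPREPHI	RFIKQGHD	YKVMGD	mouse
TRBV5*02	PKNACLG	EVICFWAN	CSIARG	mouse
TRBV12-1*01	PASMYGD	ADWWHSSF	YKFNIQ	mouse
TRBV12-1*02	MKWYNRW	QFIVGMLV	NLLRLN	mouse
TRBV12-2*01	FYHTNAE	PCPRNDIH	KIQHES	mouse
TRBV13-1*01	EYEPNII	WSHQQQWF	EGYANQ	mouse
TRBV13-2*01	YPEWNAI	VEQQNCRA	TYEVTK	mouse
TRBV13-3*01	MKQDACP	HFRVWATF	AQCTWP	mouse
TRBV13-3*02	NMLKCTM	FAHMF-CL	DQSRMI	mouse
TRBV17*01	YAASMHA	GQE-DQNI	SHLPWD	mouse
TRBV20*01	CWEC-QD	ERKDTNLI	NKYHMG	mouse
TRBV23*01	WMLKYNT	VRVH-VEV	SQHPLI	mouse
TRBV26*01	TSGWFAT	QNCY-WEH	AIMQHK	mouse
TRBV29*01	TYRI-MT	AQWTH-VN	DADGNM	mouse
TRBV31*01	RKLTKAY	HDDFAYHA	EGHMKI	mouse
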