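chrom	pos	ref	alt	maf_1000g	maf_nhlbi	maf_exac
2	2000124	G	A	0.0027898348806973494	0.0027898348806973494	0.0027898348806973494
2	2000835	C	G	0.0017160568952764737	0.0017160568952764737	0.0017160568952764737
2	2000931	A	T	0.0018712583915805108	0.0018712583915805108	0.0018712583915805108
3	3000058	G	C	0.0032375989329198798	0.0032375989329198798	0.0032375989329198798
3	3002761	G	T	0.0003717560422746284	0.0003717560422746284	0.0003717560422746284
3	3003949	G	A	0.0004756530515716698	0.0004756530515716698	0.0004756530515716698
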