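bait	prey	sulfur	pyruvate	rank	rescued
TK1123	TK0574	true	true	5	false
TK1123	TK0789	true	true	5	false
TK1123	TK0930	true	true	4	false
TK1123	TK0953	true	true	5	false
TK1123	TK1328	true	true	4	false
TK1123	TK2012	true	true	5	false
TK1123	TK2093	true	true	5	false
TK1123	TK2106	true	true	4	false
TK1123	TK1056	true	true	4	false
TK1129	TK2012	true	true	5	false
TK1129	TK1056	true	true	4	false
TK1215	TK0574	true	true	5	false
TK1215	TK0789	true	true	4	false
TK1215	TK0930	true	true	5	false
TK1215	TK0953	true	true	4	false
TK1215	TK1328	true	true	5	false
TK1215	TK2012	true	true	5	false
TK1215	TK2093	true	true	5	false
TK1215	TK2106	true	true	5	false
TK1215	TK1056	true	true	5	false
TK2075	TK2074	true	true	5	false
TK2077	TK0574	true	true	5	false
TK2077	TK0789	true	true	5	false
TK2077	TK0930	true	true	4	false
TK2077	TK0953	true	true	5	false
TK2077	TK1328	true	true	5	false
TK2077	TK2012	true	true	5	false
TK2077	TK2093	true	true	4	false
TK2077	TK2106	true	true	5	false
TK2077	TK0826	true	true	5	false
TK2077	TK2074	true	true	5	false
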