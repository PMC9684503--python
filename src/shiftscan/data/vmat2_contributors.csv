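system_id,vmat2_state,ligand,ligand_state,rank,residue
RSP_deprot:CYT,CYT,RSP,deprot,1,I396
RSP_deprot:CYT,CYT,RSP,deprot,2,L229
RSP_deprot:CYT,CYT,RSP,deprot,3,V233
RSP_deprot:CYT,CYT,RSP,deprot,4,F335
RSP_deprot:CYT,CYT,RSP,deprot,5,Y342
(R)-RSP+:CYT,CYT,RSP,(R)+,1,Y342
(R)-RSP+:CYT,CYT,RSP,(R)+,2,L37
(R)-RSP+:CYT,CYT,RSP,(R)+,3,M205
(R)-RSP+:CYT,CYT,RSP,(R)+,4,I396
(R)-RSP+:CYT,CYT,RSP,(R)+,5,A338
(R)-RSP+:CYT,CYT,RSP,(R)+,6,S339
(S)-RSP+:CYT,CYT,RSP,(S)+,1,V233
(S)-RSP+:CYT,CYT,RSP,(S)+,2,Y342
(S)-RSP+:CYT,CYT,RSP,(S)+,3,L229
(S)-RSP+:CYT,CYT,RSP,(S)+,4,F430
(S)-RSP+:CYT,CYT,RSP,(S)+,5,I396
(S)-RSP+:CYT,CYT,RSP,(S)+,6,F335
(S)-RSP+:CYT,CYT,RSP,(S)+,7,L226
(S)-RSP+:CYT,CYT,RSP,(S)+,8,T38
(S)-RSP+:CYT,CYT,RSP,(S)+,9,A230
TBZ_deprot:CYT,CYT,TBZ,deprot,1,M311
TBZ_deprot:CYT,CYT,TBZ,deprot,2,F136
TBZ_deprot:CYT,CYT,TBZ,deprot,3,F450
TBZ_deprot:CYT,CYT,TBZ,deprot,4,G133
TBZ_deprot:CYT,CYT,TBZ,deprot,5,A315
TBZ_deprot:CYT,CYT,TBZ,deprot,6,I318
TBZ_deprot:CYT,CYT,TBZ,deprot,7,P438
TBZ_deprot:CYT,CYT,TBZ,deprot,8,V132
(R)-TBZ+:CYT,CYT,TBZ,(R)+,1,E313
(R)-TBZ+:CYT,CYT,TBZ,(R)+,2,Y342
(R)-TBZ+:CYT,CYT,TBZ,(R)+,3,F335
(R)-TBZ+:CYT,CYT,TBZ,(R)+,4,A338
(R)-TBZ+:CYT,CYT,TBZ,(R)+,5,V233
(R)-TBZ+:CYT,CYT,TBZ,(R)+,6,S339
(R)-TBZ+:CYT,CYT,TBZ,(R)+,7,A230
(S)-TBZ+:CYT,CYT,TBZ,(S)+,1,Y342
(R)-SMT+:CYT,CYT,SMT,(R)+,1,E313
(R)-SMT+:CYT,CYT,SMT,(R)+,2,N389
(R)-SMT+:CYT,CYT,SMT,(R)+,3,K139
(R)-SMT+:CYT,CYT,SMT,(R)+,4,Y434
(R)-SMT+:CYT,CYT,SMT,(R)+,5,L316
(R)-SMT+:CYT,CYT,SMT,(R)+,6,V392
(R)-SMT+:CYT,CYT,SMT,(R)+,7,F430
(S)-SMT+:CYT,CYT,SMT,(S)+,1,E313
(S)-SMT+:CYT,CYT,SMT,(S)+,2,Y434
(S)-SMT+:CYT,CYT,SMT,(S)+,3,P238
(S)-SMT+:CYT,CYT,SMT,(S)+,4,L331
(S)-SMT+:CYT,CYT,SMT,(S)+,5,P317
(S)-SMT+:CYT,CYT,SMT,(S)+,6,V233
(S)-SMT+:CYT,CYT,SMT,(S)+,7,Q143
(S)-SMT+:CYT,CYT,SMT,(S)+,8,P237
(S)-SMT+:CYT,CYT,SMT,(S)+,9,F430
(S)-SMT+:CYT,CYT,SMT,(S)+,10,F335
(S)-SMT+:CYT,CYT,SMT,(S)+,11,L316
(S)-SMT+:CYT,CYT,SMT,(S)+,12,K139
ZPS_deprot:CYT,CYT,ZPS,deprot,1,F136
ZPS_deprot:CYT,CYT,ZPS,deprot,2,P314
ZPS_deprot:CYT,CYT,ZPS,deprot,3,A315
ZPS_deprot:CYT,CYT,ZPS,deprot,4,I318
ZPS_deprot:CYT,CYT,ZPS,deprot,5,F450
ZPS_deprot:CYT,CYT,ZPS,deprot,6,M311
ZPS_deprot:CYT,CYT,ZPS,deprot,7,V132
ZPS_deprot:CYT,CYT,ZPS,deprot,8,N129
ZPS_deprot:CYT,CYT,ZPS,deprot,9,P438
ZPS_deprot:CYT,CYT,ZPS,deprot,10,Y434
ZPS+:CYT,CYT,ZPS,+,1,F136
ZPS+:CYT,CYT,ZPS,+,2,M311
ZPS+:CYT,CYT,ZPS,+,3,F450
ZPS+:CYT,CYT,ZPS,+,4,P314
ZPS+:CYT,CYT,ZPS,+,5,A315
ZPS+:CYT,CYT,ZPS,+,6,I318
ZPS+:CYT,CYT,ZPS,+,7,A445
RSP_deprot:LUM,LUM,RSP,deprot,1,K328
RSP_deprot:LUM,LUM,RSP,deprot,2,Y434
RSP_deprot:LUM,LUM,RSP,deprot,3,N306
RSP_deprot:LUM,LUM,RSP,deprot,4,V233
RSP_deprot:LUM,LUM,RSP,deprot,5,T38
RSP_deprot:LUM,LUM,RSP,deprot,6,L37
RSP_deprot:LUM,LUM,RSP,deprot,7,I309
RSP_deprot:LUM,LUM,RSP,deprot,8,W329
RSP_deprot:LUM,LUM,RSP,deprot,9,F430
(R)-RSP+:LUM,LUM,RSP,(R)+,1,L226
(R)-RSP+:LUM,LUM,RSP,(R)+,2,F430
(R)-RSP+:LUM,LUM,RSP,(R)+,3,A230
(R)-RSP+:LUM,LUM,RSP,(R)+,4,L229
(R)-RSP+:LUM,LUM,RSP,(R)+,5,F335
(R)-RSP+:LUM,LUM,RSP,(R)+,6,G397
(R)-RSP+:LUM,LUM,RSP,(R)+,7,Y342
(R)-RSP+:LUM,LUM,RSP,(R)+,8,F394
(R)-RSP+:LUM,LUM,RSP,(R)+,9,V233
(R)-RSP+:LUM,LUM,RSP,(R)+,10,M205
(R)-RSP+:LUM,LUM,RSP,(R)+,11,N34
(R)-RSP+:LUM,LUM,RSP,(R)+,12,M404
(S)-RSP+:LUM,LUM,RSP,(S)+,1,F335
(S)-RSP+:LUM,LUM,RSP,(S)+,2,V233
(S)-RSP+:LUM,LUM,RSP,(S)+,3,I309
(S)-RSP+:LUM,LUM,RSP,(S)+,4,L331
(S)-RSP+:LUM,LUM,RSP,(S)+,5,L229
TBZ_deprot:LUM,LUM,TBZ,deprot,1,P317
TBZ_deprot:LUM,LUM,TBZ,deprot,2,F390
TBZ_deprot:LUM,LUM,TBZ,deprot,3,Y342
TBZ_deprot:LUM,LUM,TBZ,deprot,4,F335
TBZ_deprot:LUM,LUM,TBZ,deprot,5,M320
TBZ_deprot:LUM,LUM,TBZ,deprot,6,A338
TBZ_deprot:LUM,LUM,TBZ,deprot,7,L316
TBZ_deprot:LUM,LUM,TBZ,deprot,8,M321
(R)-TBZ+:LUM,LUM,TBZ,(R)+,1,I309
(R)-TBZ+:LUM,LUM,TBZ,(R)+,2,F335
(R)-TBZ+:LUM,LUM,TBZ,(R)+,3,L316
(R)-TBZ+:LUM,LUM,TBZ,(R)+,4,P317
(R)-TBZ+:LUM,LUM,TBZ,(R)+,5,A310
(S)-TBZ+:LUM,LUM,TBZ,(S)+,1,F335
(S)-TBZ+:LUM,LUM,TBZ,(S)+,2,L234
(S)-TBZ+:LUM,LUM,TBZ,(S)+,3,I309
(R)-SMT+:LUM,LUM,SMT,(R)+,1,D400
(R)-SMT+:LUM,LUM,SMT,(R)+,2,P314
(R)-SMT+:LUM,LUM,SMT,(R)+,3,Y342
(R)-SMT+:LUM,LUM,SMT,(R)+,4,A310
(R)-SMT+:LUM,LUM,SMT,(R)+,5,L343
(R)-SMT+:LUM,LUM,SMT,(R)+,6,T346
(R)-SMT+:LUM,LUM,SMT,(R)+,7,N306
(R)-SMT+:LUM,LUM,SMT,(R)+,8,F136
(R)-SMT+:LUM,LUM,SMT,(R)+,9,I309
(R)-SMT+:LUM,LUM,SMT,(R)+,10,G397
(R)-SMT+:LUM,LUM,SMT,(R)+,11,P438
(R)-SMT+:LUM,LUM,SMT,(R)+,12,A230
(S)-SMT+:LUM,LUM,SMT,(S)+,1,E313
(S)-SMT+:LUM,LUM,SMT,(S)+,2,Y342
(S)-SMT+:LUM,LUM,SMT,(S)+,3,N389
(S)-SMT+:LUM,LUM,SMT,(S)+,4,G393
(S)-SMT+:LUM,LUM,SMT,(S)+,5,I309
(S)-SMT+:LUM,LUM,SMT,(S)+,6,I396
(S)-SMT+:LUM,LUM,SMT,(S)+,7,I368
(S)-SMT+:LUM,LUM,SMT,(S)+,8,V392
(S)-SMT+:LUM,LUM,SMT,(S)+,9,F390
ZPS_deprot:LUM,LUM,ZPS,deprot,1,F335
ZPS_deprot:LUM,LUM,ZPS,deprot,2,L331
ZPS_deprot:LUM,LUM,ZPS,deprot,3,V233
ZPS_deprot:LUM,LUM,ZPS,deprot,4,L336
ZPS_deprot:LUM,LUM,ZPS,deprot,5,P317
ZPS_deprot:LUM,LUM,ZPS,deprot,6,G332
ZPS+:LUM,LUM,ZPS,+,1,V233
ZPS+:LUM,LUM,ZPS,+,2,Y342
ZPS+:LUM,LUM,ZPS,+,3,A230
ZPS+:LUM,LUM,ZPS,+,4,I309
ZPS+:LUM,LUM,ZPS,+,5,I396
ZPS+:LUM,LUM,ZPS,+,6,L226
ZPS+:LUM,LUM,ZPS,+,7,Y434
ZPS+:LUM,LUM,ZPS,+,8,D400
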