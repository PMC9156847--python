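child_id,method,dnm_count,maternal_age,paternal_age,fertility_status
101C,spontaneous,85,32,34,No fertility problem
102C,spontaneous,65,28,28,No fertility problem
103C,spontaneous,79,33,33,No fertility problem
105C,spontaneous,62,27,26,No fertility problem
106C,spontaneous,82,37,32,No fertility problem
107C,spontaneous,75,29,34,No fertility problem
108C,spontaneous,73,23,24,No fertility problem
112C,spontaneous,67,32,30,"Severe oligozoospermia, pregnant while waiting for treatment"
114C,spontaneous,55,30,31,"Ovulation disorder, pregnant while waiting for treatment"
201C,spontaneous,95,40,58,No fertility problem
202C,spontaneous,116,28,54,No fertility problem
205C,spontaneous,95,41,48,No fertility problem
206C,spontaneous,81,42,51,"Severe oligozoospermia, pregnant while waiting for treatment"
207C,spontaneous,104,37,56,"Unexplained infertility, pregnant while waiting for treatment"
209C,spontaneous,113,37,49,No fertility problem
210C,spontaneous,94,38,46,No fertility problem
211C,spontaneous,83,39,48,"Unexplained infertility, pregnant while waiting for treatment"
212C,spontaneous,66,35,46,"Moderate oligozoospermia, pregnant while waiting for treatment"
302C,IVF,54,30,27,Endometriosis
303C,IVF,55,28,28,Endometriosis
304C,IVF,68,28,30,Endometriosis
305C,IVF,58,30,31,Unexplained infertility
307C,IVF,74,32,32,Unexplained infertility
308C,IVF,62,27,30,Unexplained infertility
310C,IVF,71,27,31,Endometriosis
311C-1,IVF,85,32,31,Unexplained infertility
311C-2,IVF,88,35,34,Unexplained infertility
312C,IVF,78,33,34,Unexplained infertility
402C,IVF,103,37,57,Unexplained infertility
403C,IVF,89,38,47,Unexplained infertility
404C,IVF,96,41,48,Unexplained infertility
408C,IVF,106,41,46,Tubal pathology
409C,IVF,94,29,46,Cervical factor
410C,IVF,99,36,48,Unexplained infertility
414C,IVF,94,37,47,Tubal pathology
503C,ICSI-TESE,60,30,23,NOA
505C,ICSI-TESE,79,33,30,Extreme oligoasthenoteratozoospermia
506C,ICSI-TESE,72,30,30,OA based on CBAVD
507C,ICSI-TESE,65,26,30,OA based on CBAVD
508C,ICSI-TESE,91,25,30,NOA
509C,ICSI-TESE,67,27,29,NOA
510C,ICSI-TESE,66,23,26,NOA
511C,ICSI-TESE,59,26,31,NOA
601C,ICSI-TESE,80,27,47,OA after sterilisation: PESA no sperm was found
606C,ICSI-TESE,102,40,54,OA after vasovasostomy
607C,ICSI-TESE,86,25,47,OA after vasovasostomy
609C,ICSI-TESE,113,38,51,OA after sterilisation: with PESA no sperm was found
610C,ICSI-TESE,97,35,62,OA after sterilisation: with PESA no sperm was found
611C,ICSI-TESE,96,31,49,OA after sterilisation: with PESA no sperm was found
612C,ICSI-TESE,90,33,49,OA after vasovasostomy
613C,ICSI-TESE,90,39,53,OA after sterilisation: with PESA no sperm was found
614C-1,ICSI-TESE,84,38,55,OA after vasovasostomy
614C-2,ICSI-TESE,83,38,55,OA after vasovasostomy
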