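family	start	size	completeness
IS110	1,294,097		unknown
IS110	1,511,194		unknown
IS110	1,680,643		unknown
IS110	1,681,299		unknown
IS110	2,106,054		unknown
IS110	2,442,951		unknown
IS110	2,897,773		unknown
IS110	2,921,245		unknown
IS110	4,295,929		unknown
IS110	4,351,716		unknown
IS110	5,122,272		unknown
IS21	405,533		unknown
IS21	408,050		unknown
IS21	558,910		unknown
IS21	559,670		unknown
IS21	1,101,517		unknown
IS21	2,686,862		unknown
IS21	2,892,945		unknown
IS21	5,027,620		unknown
IS256	396,558		unknown
IS256	398,704		unknown
IS256	400,530		unknown
IS256	402,427		unknown
IS256	406,669		unknown
IS256	500,419		unknown
IS256	503,019		unknown
IS256	1,053,476		unknown
IS256	1,157,794		unknown
IS256	1,667,494		unknown
IS256	1,955,155		unknown
IS256	2,038,553		unknown
IS256	2,444,414		unknown
IS256	2,896,931		unknown
IS256	2,900,956		unknown
IS256	2,907,621		unknown
IS256	2,920,403		unknown
IS256	2,923,263		unknown
IS256	4,297,392		unknown
IS256	4,359,525		unknown
IS256	4,709,310		unknown
IS256	4,713,667		unknown
IS256	4,718,534		unknown
IS256	4,719,692		unknown
IS256	4,720,973		unknown
IS3	85,462		unknown
IS3	85,767		unknown
IS3	560,662		unknown
IS3	561,333		unknown
IS3	878,055		unknown
IS3	878,912		unknown
IS3	1,138,429		unknown
IS3	1,138,734		unknown
IS3	1,576,715		unknown
IS3	1,577,572		unknown
IS3	2,925,868		unknown
IS3	2,926,173		unknown
IS3	3,540,894		unknown
IS3	3,541,751		unknown
IS3	4,715,895		unknown
IS3	4,716,752		unknown
ISL3	501,440		unknown
ISL3	739,282		unknown
ISL3	740,964		unknown
ISL3	1,487,374		unknown
ISL3	2,096,180		unknown
ISL3	2,592,895		unknown
ISL3	3,224,583		unknown
ISL3	4,600,526		unknown
ISL3	4,871,301		unknown
DDE-t (IS21 family)	98,630		unknown
DDE-t (IS21 family)	4,331,611		unknown
IS21 ATPb	408,654		unknown
IS21 ATPb	558,111		unknown
IS21 ATPb	1,100,718		unknown
IS21 ATPb	2,688,283		unknown
IS21 ATPb	2,894,569		unknown
IS21 ATPb	5,026,821		unknown
DDE-ATPb	97,776		unknown
DDE-ATPb	4,330,757		unknown
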