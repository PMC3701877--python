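# Directional connections among pigeon telencephalic regions, transcribed
# row-for-row from the published connection table. Each row lists the row
# region followed by semicolon-separated statements. "-> X: refs" denotes an
# edge row-region -> X; "<- X: refs" denotes X -> row-region. Trailing
# numbers are literature citation indices and carry no graph information.
# Known typographic irregularities in the source are preserved verbatim and
# catalogued in transcription_notes.md.
AA	→ AD: 29, 34; ← AD: 29; → AI: 19; ← AI: 34; ← Ep: 12, 19; ← Field L1: 19; ← Field L3: 19; → HI: 7; → HD: 7; → MD: 7; → NCL: 19; ← NCL: 19, 34; ← NCM: 34; → NFM: 19; → StL: 19, 29; → StM: 19, 29; → TPO: 3, 34; → TuO: 29; → VP: 34
Ac	← AD: 13, 29; ← AI: 13, 29; ← APH: 13, 29; ← CPi: 9, 13, 29; ← Hp-DM: 22, 13; ← MM: 13; ← NCC: 13; ← NCL: 13, 19; ← NFM: 13; ← NMm: 13; ← NSTL: 1, 13; ← PoA: 1, 13, 29; → VP: 13, 29
AD	→ AI: 1, 19, 29; ← AI: 19, 34; → CPi: 23; ← Ep: 12, 19; ← Field L1: 19; ← Field L3: 19; → HI: 7; ← HI: 7; → HD: 7; ← HD: 28; → MD: 4, 5; ← MD: 4, 5, 28; → MM: 5; ← MM: 5; → NCL: 19; ← NCL: 1, 19, 34; ← NFL: 19; → NFM: 19; ← NMm: 19; ← NSTL: 1; → SL: 2; ← SL: 2; ← SM: 2; → StL: 1, 19, 29; ← StM: 1, 19, 29; → TPO: 3, 34; → TuO: 29; → VP: 22, 29;
AI	→ AM: 4, 19; → APH: 10; ← APH: 10; ← Ei: 12; ← Ee: 12; ← Ep: 12, 19; ← Field L1: 19; ← Field L3: 19; ← HA: 19, 28; → HI: 7, 28; ← HI: 28; → HD: 7; ← HD: 28; → MC: 5, 19; → MD: 5; ← MD: 5, 28; → MM: 5; ← MM: 5, 7; → NCC: 4; → NCL: 19, 21, 24; ← NCL: 19, 21, 24, 34; ← NCM: 1, 19; ← NFL: 19; → NFM: 19, 27, 31, 32; ← NFM: 19, 31, 32; ← NIL: 19; → NIMl: 19; ← NIMl: 19; → NMm: 19; ← NMm: 19; → SL: 2; → StL: 19, 29; → StM: 19, 29; → TPO: 3; ← TPO: 34; → TuO: 29; → VP: 29, 34
AIvm	→ Field L1: 33; → Field L3: 33; → MC: 33; ← NCL: 19, 33
AM	← NCC: 4; → NCL: 4, 19; → NSTL: 1; ← NSTL: 1; ← PoA: 1; → SL: 2; ← SL: 2; → StM: 13, 29; ← TnA: 4
APH	→ AV: 4, 19; ← AV: 10; → CDL: 2, 3, 10, 17, 19; ← CDL: 2, 3, 8, 10; ← CPi: 2; ← HA: 19, 28; → HD: 2; ← HD: 2, 10, 28; → HL: 2; ← HL: 2, 10; → Hp-DM: 2, 6, 10, 14; ← Hp-DM: 2, 6, 10, 14; → Hp-VM: 2, 6, 14; ← Hp-VM: 2, 6, 14; → NDB: 2, 10; ← NDB: 2, 8, 10, 18; ← NFL: 2; → SL: 2, 10, 17; ← SL: 2; → SM: 2, 10, 17; ← SM: 2, 8, 10; ← SpA: 10; → TnA: 2, 17; ← TnA: 2
AV	← BO: 23; → MD: 4, 5; ← MD: 4, 5; ← NCL: 19; → NIMl: 19; → NMm: 19; → StL: 29; → StM: 19, 29
Bas	→ NFM: 27, 31, 32; ← NFM: 27, 31, 32
BO	→ CDL: 23, 25; → CPi: 9, 23, 25, 26; → CPP: 23, 25; → SM: 23; → TnA: 23, 25
CDL	→ CPi: 3, 23; ← CPi: 3, 23; → HD: 3; ← HD: 3, 28; → HL: 3; ← HL: 3; → Hp-DM: 2, 3, 6, 10; ← Hp-DM: 2, 3, 6, 10; → Hp-VM: 3, 6; ← Hp-VM: 3, 6; → MD: 5; ← MD: 3, 5; → NCVl: 3; ← NCVl: 3; → NDB: 3; → NFL: 3; ← NFL: 3; → NIL: 3; ← NIL: 3; → PoA: 1, 3; ← PoA: 1, 3; → SL: 3; → StL: 3, 19, 29; → TPO: 3; ← TPO: 3;
CPi	← CPP: 9, 23; ← HD: 9, 23, 28; ← HL: 23; ← NFL: 23; ← NSTL: 1. 9, 23, 29; ← PoA: 1, 23, 29
Ee	← MVL: 5, 20, 24
Ei	→ Ep: 12, 16, 20, 24; Ei → MVL: 5, 12, 20, 24; ← MVL: 5, 12, 20, 24; ← NFL: 20, 29; → NIL: 12, 20; → StL: 12, 20
Ep	→ NCL: 19; ← NCL: 12, 19; → NFL: 12, 20, 29; → NIL: 12, 20; → TPO: 20
L1	← Field L2: 33; ← Field L3: 33; → MC: 5, 24; ←MC: 5; →NCL: 19, 33; ← NCL: 19, 33;
L2	→ Field L3: 33; ← Field L3: 33; → MC: 33; ← MC: 5, 33;
L3	→ MC: 5, 33; ← MC: 5, 33; ← NCL: 19
GP	← StL: 15, 22, 29
HA	← HD: 19, 28; ← HI: 19, 28; → HL: 28; ← HL: 28; → Hp-DM: 10; ← Hp-DM: 19; ← IHA: 19, 28, 30; → MM: 5, 19; → NCL: 19, 21, 28; ← NCL: 19; → NFL: 19, 28; → NIMl: 19, 28; ← NIMl: 11, 19; → NMm: 19, 28, 30; → StL: 28, 29; → StM: 28, 29; → TPO: 5, 19, 28
HD	→ Hp-DM: 2, 10; ← Hp-DM: 2; → MM: 5; → NCL: 19, 21, 28; → NFL: 28; → PoA: 1; ← PoA: 1; → StL: 28, 29; → StM: 19, 28, 29
HL	→ Hp-DM: 2, 10; ← Hp-DM: 2; → NCL: 19, 21; ← NCL: 19; → NFL: 28;
Hp-DM	→ Hp-VM: 2, 6, 17; ← Hp-VM: 2, 6; → NDB: 6, 10, 14, 17; ← NDB: 6, 10, 14; → NSTL: 1, 6, 17; ← PoA: 1, 2; → SL: 2, 6, 10, 17; ← SL: 2, 6; → SM: 2, 6, 14, 17; ← SM: 2, 6; ← SpA: 2; → TnA: 2, 17; ← TnA: 10
Hp-VM	→ NDB: 6, 17; ← PoA: 6; → SL: 2, 6, 10, 17; ← SL: 2, 6; ← SM: 2, 6; → TnA: 6; ← TnA: 6
MC	→ MM: 5; → NCM: 5; ← NCM: 5; → NIMl: 5, 19; ← NIMl: 5, 19, 24; → NMm: 24
MD	→ NCC: 4, 24, 28; ← NCC: 4, 24; → NCL: 5, 19, 21, 24, 28; ← NCL: 5, 24; → NCM: 4, 24, 28; → NFL: 28; → NFM: 5; ← NFM: 5; → NMm: 4, 5, 19, 28; → PoA: 4, 5; → StM: 5, 19, 24, 28, 29; → TPO: 3, 5, 28
MM	→ NCL: 5, 19; ← NCL: 19, 24; → NMm: 5, 19; ← NMm: 5; → StL: 5, 24, 29; → StM: 5, 13, 19, 24, 29
NCC	← NMm: 4; → NSTL: 1, 4; ← NSTL: 1; ← PoA: 1, 4
NCL	→ NCM: 1; ← NCM: 1, 19; ← NFL: 19; ← NFM: 19, 24, 27, 31, 32; → NIMl: 19; ← NIMl: 19, 24; → NMm: 19, 24; ← NMm: 19; → NSTL: 1, 19; ← PoA: 1, 19, 21; → StL: 19, 29; → StM: 19, 29; ← TnA: 19, 21
NCM	← NIMl: 19
NCVl	→ NSTL: 1; ← NSTL: 1; → PoA: 1; ← PoA: 1
NDB	→ SL: 2; → SM: 2; ← SM: 2
NFL	→ PoA: 1; ← PoA: 1; → StL: 20, 29; → StM: 29; → TPO: 3
NFM	← PoA: 1
NIL	→ StL: 20, 29; → TPO: 3
NIMl	→ StL: 19
NMm	→ StM: 13, 19, 29
NSTL	→ PoA: 1; ← PoA: 29; → SL: 1, 2; ← SL: 1, 2; → SpA: 1; ← SpA: 1; → TnA: 1; ← TnA: 29; → TuO: 1; ← TuO: 1
PoA	→ SL: 1, 2; → SpA: 1; → StL: 1; → TuO: 1, 29; ← TuO: 1
SL	→ SM: 2; ← SM: 2; ← TnA: 2, 25; ← TuO: 2; → VP: 2; ← VP: 2
SM	→ TuO: 2; ← TuO: 2; → VP: 2; ← VP: 2
StL	← TPO: 3, 19, 20, 29; → VP: 15, 29
StM	→ VP: 22, 29
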