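animal	subgroup	proximal	distal
L1	lean2	q	q
L2	lean2	Q	q
L3	lean1	q	Q
L4	lean1	Q	q
L5	lean1	Q	q
L6	lean1	q	x
L7	lean2	Q	x
L8	lean1	q	Q
L9	mixed	q	q
L10	lean1	x	q
L11	lean1	x	q
L12	lean1	q	q
L13	fat2	x	Q
L14	lean1	Q	q
L15	lean1	x	Q
L16	lean2	q	x
L17	lean2	Q	q
L18	mixed	Q	Q
L19	lean2	Q	q
L20	fat2	q	q
I1	mixed	x	Q
I2	fat2	x	Q
I3	mixed	q	q
I4	mixed	Q	Q
I5	mixed	Q	q
F1	fat1	Q	Q
F2	mixed	Q	Q
F3	fat2	Q	Q
F4	fat2	Q	Q
F5	fat1	Q	x
F6	fat1	q	q
F7	fat1	Q	Q
F8	mixed	x	Q
F9	fat1	Q	x
F10	fat1	q	q
F11	fat2	x	q
F12	fat2	Q	Q
F13	mixed	q	q
F14	fat1	x	Q
F15	fat2	x	Q
F16	lean2	q	q
F17	fat1	x	Q
F18	fat2	Q	Q
F19	fat2	Q	Q
F20	mixed	q	Q
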