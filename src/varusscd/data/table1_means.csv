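method,measure,condition,configuration,mean_mm,sd_mm
manual,manmean,intact,UL,7.8,1.4
manual,manmean,intact,LO,9.9,1.8
manual,manmean,LCL,UL,8.0,1.5
manual,manmean,LCL,LO,11.2,2.0
manual,manmean,LCL+PT,UL,8.1,1.3
manual,manmean,LCL+PT,LO,11.7,1.8
manual,manmean,LCL+PT+PFL,UL,8.2,1.4
manual,manmean,LCL+PT+PFL,LO,12.1,1.8
manual,manmean,LCL+PT+PFL+ACL,UL,8.7,1.2
manual,manmean,LCL+PT+PFL+ACL,LO,12.5,1.8
manual,ml1,intact,UL,6.6,1.4
manual,ml1,intact,LO,8.7,1.6
manual,ml1,LCL,UL,6.6,1.6
manual,ml1,LCL,LO,10.2,1.8
manual,ml1,LCL+PT,UL,7.0,1.4
manual,ml1,LCL+PT,LO,10.7,1.8
manual,ml1,LCL+PT+PFL,UL,6.9,1.5
manual,ml1,LCL+PT+PFL,LO,11.0,1.7
manual,ml1,LCL+PT+PFL+ACL,UL,7.4,1.6
manual,ml1,LCL+PT+PFL+ACL,LO,11.4,1.8
manual,ml2,intact,UL,6.6,1.6
manual,ml2,intact,LO,8.6,1.7
manual,ml2,LCL,UL,6.7,1.6
manual,ml2,LCL,LO,10.2,2.0
manual,ml2,LCL+PT,UL,6.8,1.4
manual,ml2,LCL+PT,LO,10.6,1.9
manual,ml2,LCL+PT+PFL,UL,7.1,1.5
manual,ml2,LCL+PT+PFL,LO,10.8,1.9
manual,ml2,LCL+PT+PFL+ACL,UL,7.5,1.3
manual,ml2,LCL+PT+PFL+ACL,LO,11.2,2.0
manual,ml3,intact,UL,7.0,2.0
manual,ml3,intact,LO,8.9,2.4
manual,ml3,LCL,UL,7.2,2.1
manual,ml3,LCL,LO,10.2,2.6
manual,ml3,LCL+PT,UL,7.3,2.0
manual,ml3,LCL+PT,LO,10.5,2.4
manual,ml3,LCL+PT+PFL,UL,7.5,2.2
manual,ml3,LCL+PT+PFL,LO,10.9,2.4
manual,ml3,LCL+PT+PFL+ACL,UL,8.1,1.7
manual,ml3,LCL+PT+PFL+ACL,LO,11.2,2.4
manual,ap1,intact,UL,10.5,1.4
manual,ap1,intact,LO,13.1,2.1
manual,ap1,LCL,UL,10.7,1.5
manual,ap1,LCL,LO,13.9,2.4
manual,ap1,LCL+PT,UL,10.6,1.5
manual,ap1,LCL+PT,LO,14.4,2.4
manual,ap1,LCL+PT+PFL,UL,11.1,1.6
manual,ap1,LCL+PT+PFL,LO,14.8,2.4
manual,ap1,LCL+PT+PFL+ACL,UL,11.7,1.3
manual,ap1,LCL+PT+PFL+ACL,LO,15.2,2.2
manual,ap2,intact,UL,6.8,1.6
manual,ap2,intact,LO,9.0,2.0
manual,ap2,LCL,UL,7.0,1.7
manual,ap2,LCL,LO,10.3,2.0
manual,ap2,LCL+PT,UL,7.3,1.4
manual,ap2,LCL+PT,LO,10.7,1.9
manual,ap2,LCL+PT+PFL,UL,7.5,1.5
manual,ap2,LCL+PT+PFL,LO,11.2,1.9
manual,ap2,LCL+PT+PFL+ACL,UL,7.8,1.4
manual,ap2,LCL+PT+PFL+ACL,LO,11.4,2.1
manual,ap3,intact,UL,9.0,1.7
manual,ap3,intact,LO,10.7,1.8
manual,ap3,LCL,UL,9.5,1.5
manual,ap3,LCL,LO,12.7,1.6
manual,ap3,LCL+PT,UL,9.5,1.5
manual,ap3,LCL+PT,LO,13.5,1.5
manual,ap3,LCL+PT+PFL,UL,9.4,1.6
manual,ap3,LCL+PT+PFL,LO,13.9,1.7
manual,ap3,LCL+PT+PFL+ACL,UL,9.5,1.5
manual,ap3,LCL+PT+PFL+ACL,LO,14.3,1.9
computational,compmean,intact,UL,8.7,1.4
computational,compmean,intact,LO,10.8,1.8
computational,compmean,LCL,UL,8.9,1.6
computational,compmean,LCL,LO,12.4,2.1
computational,compmean,LCL+PT,UL,9.0,1.3
computational,compmean,LCL+PT,LO,12.7,1.8
computational,compmean,LCL+PT+PFL,UL,9.2,1.2
computational,compmean,LCL+PT+PFL,LO,13.0,1.8
computational,compmean,LCL+PT+PFL+ACL,UL,9.5,1.3
computational,compmean,LCL+PT+PFL+ACL,LO,13.5,1.9
computational,ml1,intact,UL,6.5,1.2
computational,ml1,intact,LO,8.7,1.6
computational,ml1,LCL,UL,6.8,1.5
computational,ml1,LCL,LO,10.4,1.9
computational,ml1,LCL+PT,UL,6.8,1.4
computational,ml1,LCL+PT,LO,10.8,1.6
computational,ml1,LCL+PT+PFL,UL,6.9,1.3
computational,ml1,LCL+PT+PFL,LO,11.1,1.6
computational,ml1,LCL+PT+PFL+ACL,UL,7.3,1.5
computational,ml1,LCL+PT+PFL+ACL,LO,11.6,1.8
computational,ml2,intact,UL,6.6,1.4
computational,ml2,intact,LO,8.7,1.8
computational,ml2,LCL,UL,6.7,1.6
computational,ml2,LCL,LO,10.0,2.1
computational,ml2,LCL+PT,UL,7.0,1.4
computational,ml2,LCL+PT,LO,10.4,1.8
computational,ml2,LCL+PT+PFL,UL,7.0,1.3
computational,ml2,LCL+PT+PFL,LO,10.9,1.7
computational,ml2,LCL+PT+PFL+ACL,UL,7.5,1.3
computational,ml2,LCL+PT+PFL+ACL,LO,11.3,2.0
computational,ml3,intact,UL,7.0,2.2
computational,ml3,intact,LO,9.0,2.5
computational,ml3,LCL,UL,7.1,2.2
computational,ml3,LCL,LO,10.0,2.8
computational,ml3,LCL+PT,UL,7.2,1.9
computational,ml3,LCL+PT,LO,10.5,2.5
computational,ml3,LCL+PT+PFL,UL,7.5,1.9
computational,ml3,LCL+PT+PFL,LO,10.6,2.7
computational,ml3,LCL+PT+PFL+ACL,UL,8.0,1.8
computational,ml3,LCL+PT+PFL+ACL,LO,11.1,2.4
computational,ap1,intact,UL,10.8,1.0
computational,ap1,intact,LO,13.4,2.2
computational,ap1,LCL,UL,10.9,1.2
computational,ap1,LCL,LO,14.2,2.2
computational,ap1,LCL+PT,UL,10.9,1.2
computational,ap1,LCL+PT,LO,14.2,1.9
computational,ap1,LCL+PT+PFL,UL,11.1,1.2
computational,ap1,LCL+PT+PFL,LO,14.8,2.0
computational,ap1,LCL+PT+PFL+ACL,UL,11.8,1.3
computational,ap1,LCL+PT+PFL+ACL,LO,15.3,2.2
computational,ap2,intact,UL,6.9,1.2
computational,ap2,intact,LO,9.0,1.7
computational,ap2,LCL,UL,7.1,1.4
computational,ap2,LCL,LO,10.4,2.2
computational,ap2,LCL+PT,UL,7.3,1.4
computational,ap2,LCL+PT,LO,10.5,1.8
computational,ap2,LCL+PT+PFL,UL,7.2,1.2
computational,ap2,LCL+PT+PFL,LO,11.1,1.7
computational,ap2,LCL+PT+PFL+ACL,UL,7.8,1.2
computational,ap2,LCL+PT+PFL+ACL,LO,11.6,2.0
computational,ap3,intact,UL,7.4,1.9
computational,ap3,intact,LO,9.5,1.7
computational,ap3,LCL,UL,7.9,1.8
computational,ap3,LCL,LO,11.4,2.1
computational,ap3,LCL+PT,UL,7.8,1.6
computational,ap3,LCL+PT,LO,12.4,1.8
computational,ap3,LCL+PT+PFL,UL,8.2,1.6
computational,ap3,LCL+PT+PFL,LO,12.4,2.0
computational,ap3,LCL+PT+PFL+ACL,UL,8.0,1.7
computational,ap3,LCL+PT+PFL+ACL,LO,12.9,1.9
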