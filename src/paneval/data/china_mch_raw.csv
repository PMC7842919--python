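alternative,X1,X2,X3,X4,X5,X6
2004,48.3,88.3,76.4,89.7,85.9,82.8
2005,47.7,88.5,76.7,89.8,86.0,85.9
2006,41.1,88.2,76.5,89.7,85.7,88.4
2007,36.6,89.3,77.3,90.9,86.7,91.7
2008,34.2,89.3,78.1,91.0,87.0,94.5
2009,31.9,90.9,80.9,92.2,88.7,96.3
2010,30.0,92.9,84.1,94.1,90.8,97.8
2011,26.1,93.8,85.2,93.7,91.0,98.7
2012,24.5,94.8,87.6,95.0,92.6,99.2
2013,23.2,95.7,89.5,95.6,93.5,99.5
2014,21.7,95.8,90.0,96.2,93.9,99.6
2015,20.1,96.4,91.5,96.5,94.5,99.7
2016,19.9,96.6,91.6,96.6,94.6,99.8
2017,19.6,96.6,89.6,96.5,94.0,99.9
2018,18.3,92.5,89.9,96.6,93.8,99.9
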